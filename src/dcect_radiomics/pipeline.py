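"""End-to-end pipeline: simulate -> extract -> select -> concordance ->
prune -> descriptive statistics -> classify, with a reproducibility manifest.

Each stage writes its artifacts under the configured output directory; a
failure aborts with the stage name while earlier artifacts are preserved.
Rerunning with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .phantom import PhantomSpec, build_cohort
from .features import extract_feature_vector
from .tables import FeatureTable
from .concordance import (select_phase_sequences, interobserver_reproducible,
                          pairwise_sequence_matrix, intra_phase_reproducible,
                          prune_correlated, dice_coefficient, PHASES)
from .grading import run_grading_pipeline, descriptive_statistics

log = logging.getLogger("dcect")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def phantom_spec_from_config(config: RunConfig) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=tuple(config.grid_shape), lesion_radii=(10.0, 9.0, 9.0),
        n_nce=config.n_nce, n_lap=config.n_lap, n_pvp=config.n_pvp,
        observer_target_dsc=config.observer_target_dsc, noise_sd=config.noise_sd,
        drift_per_sequence=config.drift_per_sequence,
        baseline_jitter_sd=6.0, amplitude_jitter_sd=0.2, radii_jitter_frac=0.15,
    )


def extract_cohort_table(cases, config: RunConfig | None = None,
                         radiologists=("R1", "R2"), phases=PHASES) -> FeatureTable:
    """Extract the full registry for every (patient, observer, selected
    sequence); the selection rule is applied per patient first."""
    bin_width = config.bin_width_hu if config else 25.0
    entries = []
    for case in cases:
        s = case.series
        available = {p: s.phase_indices(p) for p in PHASES}
        sel = select_phase_sequences(available)
        for phase, pos in sel.all_slots():
            if phase not in phases:
                continue
            vol = s.volumes[pos]
            slot = sel.all_slots().index((phase, pos))
            for rad in radiologists:
                mask = case.observer1_mask if rad == "R1" else case.observer2_mask
                fv = extract_feature_vector(vol, mask, spacing=s.spacing,
                                            bin_width=bin_width)
                entries.append((case.patient_id, rad, phase, slot, fv))
    return FeatureTable.from_feature_vectors(entries)


def run_pipeline(config: RunConfig) -> Path:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.txt").write_text(config.echo() + "\n")
    log.info("run config hash %s\n%s", config.config_hash(), config.echo())

    manifest = {"config_hash": config.config_hash(), "stages": {},
                "seeds": {s: config.stage_seed(s)
                          for s in ("simulate", "split", "smote", "rfe", "model")}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return result
        return deco

    @stage("simulate")
    def cases_and_manifest():
        spec = phantom_spec_from_config(config)
        return build_cohort(config.n_patients, spec,
                            grade_fractions=tuple(config.grade_fractions),
                            seed=config.stage_seed("simulate"))

    cases, cohort_manifest = cases_and_manifest
    cohort_manifest.to_csv(out / "cohort_manifest.csv", index=False)
    manifest["stages"]["simulate"]["n_patients"] = len(cases)

    @stage("extract")
    def table():
        t = extract_cohort_table(cases, config)
        t.to_csv(out / "feature_table.csv")
        return t

    manifest["stages"]["extract"]["rows"] = len(table.df)

    @stage("dice")
    def mean_dsc():
        vals = [dice_coefficient(c.observer1_mask, c.observer2_mask) for c in cases]
        return float(np.mean(vals))

    manifest["stages"]["dice"]["mean_dsc"] = round(mean_dsc, 4)

    @stage("concordance")
    def concordance_results():
        t1 = table.radiologist("R1")
        t2 = table.radiologist("R2")
        inter = {}
        for phase in PHASES:
            rep = interobserver_reproducible(t1, t2, phase, config.ccc_cutoff)
            rep.to_frame().to_csv(out / f"interobserver_{phase}.csv")
            inter[phase] = rep.reproducible_features()
        pairwise = {}
        for rad in ("R1", "R2"):
            counts, _ = pairwise_sequence_matrix(table.radiologist(rad), config.ccc_cutoff)
            counts.to_csv(out / f"pairwise_counts_{rad}.csv")
            pairwise[rad] = counts
        intra = {rad: {phase: intra_phase_reproducible(table.radiologist(rad),
                                                       phase, config.ccc_cutoff)
                       for phase in PHASES} for rad in ("R1", "R2")}
        with open(out / "intraphase.json", "w") as fh:
            json.dump(intra, fh, indent=1)
        return inter, pairwise, intra

    inter, pairwise, intra = concordance_results
    manifest["stages"]["concordance"]["interobserver_counts"] = {
        p: len(v) for p, v in inter.items()}

    @stage("prune")
    def pruned():
        res = {}
        for phase in PHASES:
            feats = inter[phase]
            if len(feats) < 2:
                res[phase] = feats
                continue
            mat = table.radiologist("R1").patient_matrix(phase, feats)
            res[phase] = prune_correlated(mat, config.spearman_threshold)
        with open(out / "pruned_features.json", "w") as fh:
            json.dump(res, fh, indent=1)
        return res

    manifest["stages"]["prune"]["counts"] = {p: len(v) for p, v in pruned.items()}

    grades = pd.Series({c.patient_id: c.grade for c in cases})

    @stage("stats")
    def stats_tables():
        frames = []
        for rad in ("R1", "R2"):
            for phase in PHASES:
                feats = intra[rad][phase]
                if not feats:
                    continue
                mat = table.radiologist(rad).patient_matrix(phase, feats)
                df = descriptive_statistics(mat, grades)
                df.insert(0, "radiologist", rad)
                df.insert(1, "phase", phase)
                frames.append(df)
        all_stats = (pd.concat(frames, ignore_index=True) if frames
                     else pd.DataFrame())
        all_stats.to_csv(out / "descriptive_statistics.csv", index=False)
        return all_stats

    @stage("classify")
    def model_reports():
        reports = {}
        train_n = min(config.train_n, len(cases) - config.test_n)
        test_n = len(cases) - train_n
        for rad in ("R1", "R2"):
            for phase in PHASES:
                feats = intra[rad][phase]
                if len(feats) < 1:
                    continue
                mat = table.radiologist(rad).patient_matrix(phase, feats)
                try:
                    rep = run_grading_pipeline(mat, grades, train_n, test_n,
                                               config.max_features,
                                               seed=config.stage_seed("model"))
                except ValueError as exc:
                    log.warning("classify %s/%s skipped: %s", rad, phase, exc)
                    continue
                reports[f"{rad}_{phase}"] = rep.to_dict()
        with open(out / "model_reports.json", "w") as fh:
            json.dump(reports, fh, indent=1)
        return reports

    manifest["stages"]["classify"]["models"] = sorted(model_reports)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
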