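"""Concordance machinery: Lin's CCC, Dice, phase-sequence selection,
inter-observer / inter-sequence / intra-phase reproducibility, and
Spearman-based pruning of redundant features.

A feature is called *reproducible* over a set of pairwise comparisons when
its CCC is at or above the cutoff (default 0.90) for **every** pair — the
strict reading of "concordant across the sequences"; a mean-aggregation mode
is exposed for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CCC_CUTOFF = 0.90
SPEARMAN_THRESHOLD = 0.90
PHASES = ("NCE", "L-AP", "PVP")


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).

    Both vectors constant and equal -> 1 (perfect agreement); the formula's
    limit gives 0 whenever only one vector is constant or the constants
    differ.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 paired values, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both constant and equal
    return float(2.0 * sxy / denom)


def _ccc_pair_matrix(values: np.ndarray) -> np.ndarray:
    """CCC between every pair of rows of ``values`` (rows = conditions,
    columns = patients), vectorized over one feature at a time."""
    v = np.asarray(values, dtype=np.float64)
    m = v.mean(axis=1, keepdims=True)
    c = v - m
    s2 = (c ** 2).mean(axis=1)
    cov = (c @ c.T) / v.shape[1]
    denom = s2[:, None] + s2[None, :] + (m - m.T) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ccc = np.where(denom > 0, 2.0 * cov / np.where(denom > 0, denom, 1.0), 1.0)
    return ccc


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks -> 1 (warned)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; DSC defined as 1")
        return 1.0
    return float(2.0 * int((a & b).sum()) / (na + nb))


@dataclass(frozen=True)
class SequenceSelection:
    """Per-patient selected sequence positions: 2 NCE + 7 L-AP + 7 PVP."""

    nce: tuple[int, ...]
    lap: tuple[int, ...]
    pvp: tuple[int, ...]

    def all_slots(self) -> list[tuple[str, int]]:
        return ([("NCE", i) for i in self.nce] + [("L-AP", i) for i in self.lap]
                + [("PVP", i) for i in self.pvp])

    def __post_init__(self):
        assert len(self.nce) == 2 and len(self.lap) == 7 and len(self.pvp) == 7


def _first_middle_last(idx: list[int], phase: str) -> tuple[int, ...]:
    n = len(idx)
    if n < 7:
        raise ValueError(f"phase {phase} needs >= 7 sequences, got {n}")
    if n == 7:
        return tuple(idx)
    m = n // 2
    picks = [0, 1, m - 1, m, m + 1, n - 2, n - 1]
    return tuple(idx[p] for p in picks)


def select_phase_sequences(available: dict[str, list[int]]) -> SequenceSelection:
    """Apply the selection rule: first two NCE; first two + middle three +
    last two for L-AP and PVP (middle three centered on floor(n/2))."""
    for phase, need in (("NCE", 2), ("L-AP", 7), ("PVP", 7)):
        if len(available.get(phase, [])) < need:
            raise ValueError(
                f"phase {phase} needs >= {need} sequences, got {len(available.get(phase, []))}")
    nce = tuple(sorted(available["NCE"])[:2])
    lap = _first_middle_last(sorted(available["L-AP"]), "L-AP")
    pvp = _first_middle_last(sorted(available["PVP"]), "PVP")
    return SequenceSelection(nce=nce, lap=lap, pvp=pvp)


@dataclass
class ConcordanceReport:
    """Per-feature concordance over a set of pairwise comparisons."""

    per_pair: pd.DataFrame      # rows = features, columns = comparison labels
    cutoff: float
    comparison: str
    aggregate: str = "min"      # "min" (default, strict) or "mean"

    @property
    def summary_ccc(self) -> pd.Series:
        agg = self.per_pair.min(axis=1) if self.aggregate == "min" else self.per_pair.mean(axis=1)
        return agg

    @property
    def reproducible(self) -> pd.Series:
        return self.summary_ccc >= self.cutoff

    def reproducible_features(self) -> list[str]:
        r = self.reproducible
        return sorted(r.index[r])

    def to_frame(self) -> pd.DataFrame:
        df = self.per_pair.copy()
        df["min_ccc"] = self.per_pair.min(axis=1)
        df["reproducible"] = self.reproducible
        return df


def _wide_values(table: pd.DataFrame, feature_cols: list[str] | None = None):
    """Long FeatureTable records -> dict (radiologist, phase, seq_index) ->
    DataFrame patients x features."""
    from .tables import FeatureTable
    if isinstance(table, FeatureTable):
        table = table.df
    return table


def interobserver_reproducible(t1, t2, phase: str | None = None,
                               cutoff: float = CCC_CUTOFF,
                               aggregate: str = "min") -> ConcordanceReport:
    """Per-feature CCC between the two observers' value vectors (across
    patients), one comparison per shared selected sequence in ``phase``
    (all phases when None). Reproducible = every comparison's CCC >= cutoff.
    """
    from .tables import FeatureTable
    w1 = t1.wide() if isinstance(t1, FeatureTable) else t1
    w2 = t2.wide() if isinstance(t2, FeatureTable) else t2

    keys = sorted(set(w1.keys()) & set(w2.keys()))
    if phase is not None:
        keys = [k for k in keys if k[0] == phase]
    if not keys:
        raise ValueError(f"no shared sequences for phase {phase!r}")

    cols = {}
    for key in keys:
        a, b = w1[key], w2[key]
        common = a.index.intersection(b.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 shared patients for sequence {key}")
        a = a.loc[common]
        b = b.loc[common]
        cols[f"{key[0]}#{key[1]}"] = pd.Series(
            {f: lin_ccc(a[f].values, b[f].values) for f in a.columns})
    per_pair = pd.DataFrame(cols)
    return ConcordanceReport(per_pair=per_pair, cutoff=cutoff,
                             comparison=f"interobserver[{phase or 'all'}]",
                             aggregate=aggregate)


def pairwise_sequence_matrix(t, cutoff: float = CCC_CUTOFF):
    """Counts of reproducible features for every pair of the 16 selected
    sequence slots of one observer's table.

    Returns (count_matrix DataFrame 16x16, per-pair CCC panel
    features x pairs). The diagonal holds the total feature count.
    """
    from .tables import FeatureTable
    wide = t.wide() if isinstance(t, FeatureTable) else t
    keys = sorted(wide.keys(), key=lambda k: (PHASES.index(k[0]), k[1]))
    patients = wide[keys[0]].index
    feats = list(wide[keys[0]].columns)
    if len(patients) < 3:
        raise ValueError("need >= 3 patients")
    for k in keys:
        missing = set(patients) - set(wide[k].index)
        if missing:
            raise ValueError(f"sequence {k} missing patients: {sorted(missing)}")

    stack = np.stack([wide[k].loc[patients, feats].values for k in keys])  # seq x pat x feat
    n_seq = len(keys)
    counts = np.zeros((n_seq, n_seq), dtype=int)
    ccc_panel = {}
    for f_idx, f in enumerate(feats):
        ccc = _ccc_pair_matrix(stack[:, :, f_idx])
        ccc_panel[f] = ccc
        counts += (ccc >= cutoff).astype(int)
    np.fill_diagonal(counts, len(feats))
    labels = [f"{p}#{i}" for p, i in keys]
    return pd.DataFrame(counts, index=labels, columns=labels), ccc_panel


def intra_phase_reproducible(t, phase: str, cutoff: float = CCC_CUTOFF) -> list[str]:
    """Features whose CCC >= cutoff for every within-phase pair of selected
    sequences (1 pair for NCE, 21 for L-AP / PVP)."""
    from .tables import FeatureTable
    wide = t.wide() if isinstance(t, FeatureTable) else t
    keys = sorted([k for k in wide.keys() if k[0] == phase], key=lambda k: k[1])
    if len(keys) < 2:
        raise ValueError(f"phase {phase} has fewer than 2 selected sequences")
    patients = wide[keys[0]].index
    feats = list(wide[keys[0]].columns)
    stack = np.stack([wide[k].loc[patients, feats].values for k in keys])
    out = []
    n = len(keys)
    iu = np.triu_indices(n, k=1)
    for f_idx, f in enumerate(feats):
        ccc = _ccc_pair_matrix(stack[:, :, f_idx])
        if (ccc[iu] >= cutoff).all():
            out.append(f)
    return sorted(out)


def _spearman_abs(df: pd.DataFrame, warn_constant: bool = True) -> pd.DataFrame:
    """|Spearman rho| matrix; constant columns correlate 0 with everything."""
    const = df.std(ddof=0) == 0
    if const.any() and warn_constant:
        warnings.warn(f"constant feature columns treated as correlation 0: "
                      f"{sorted(df.columns[const])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = df.rank(method="average").corr(method="pearson")  # Spearman via midranks
    rho = rho.abs().fillna(0.0)
    for c in df.columns[const]:
        rho.loc[c, :] = 0.0
        rho.loc[:, c] = 0.0
    np.fill_diagonal(rho.values, 1.0)
    return rho


def prune_correlated(values: pd.DataFrame, threshold: float = SPEARMAN_THRESHOLD,
                     ) -> list[str]:
    """Iteratively remove one member of the most-correlated feature pair.

    While any pair of retained features has |Spearman rho| > threshold, take
    the pair with the largest |rho| (lexicographic tie-break) and drop the
    member with the higher mean |rho| against all currently retained
    features (lexicographic tie-break). Returns the retained names sorted.
    """
    if values.shape[0] < 3:
        raise ValueError("need >= 3 rows (patients)")
    retained = sorted(values.columns)
    first_pass = True
    while len(retained) > 1:
        rho = _spearman_abs(values[retained], warn_constant=first_pass)
        first_pass = False
        r = rho.values.copy()
        np.fill_diagonal(r, 0.0)
        if r.max() <= threshold:
            break
        pairs = np.argwhere(np.isclose(r, r.max()))
        pairs = [(retained[i], retained[j]) for i, j in pairs if i < j]
        a, b = sorted(pairs)[0]
        mean_a = rho.loc[a, [f for f in retained if f != a]].mean()
        mean_b = rho.loc[b, [f for f in retained if f != b]].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        retained.remove(drop)
    return retained
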