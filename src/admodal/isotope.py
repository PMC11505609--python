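"""Stable-isotope (13C) enrichment analytics for GC-MS mass-isotopomer data.

A metabolite with ``n`` carbons measured by GC-MS yields a mass-isotopomer
distribution (MID): fractional abundances of the isotopologues M+0 .. M+n,
where M+X is X mass units heavier than the unlabeled molecule. Before any
biological interpretation the measured MID must be corrected for naturally
occurring 13C (~1.07% of terrestrial carbon), which smears tracer-derived
label upward in mass. After correction the module computes

* MCL (molecular carbon labeling) — the weighted average fraction of labeled
  carbons, ``sum(i * f_i) / n``, a single per-metabolite enrichment score;
* M+X percentages — ``100 * f_X`` for individual isotopologues;
* group summaries (mean +/- SD) and two-group unpaired t-tests, the layout
  used when comparing 5xFAD against wild-type slices per substrate/region.

Correction covers the carbon skeleton only; contributions from
derivatization-agent atoms are not modeled (the derivative formulas would be
required and are metabolite/protocol specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import comb

__all__ = [
    "P_NATURAL_13C",
    "MID",
    "CorrectionMatrix",
    "correction_matrix",
    "convolve_natural_abundance",
    "correct_mid",
    "mcl",
    "mx_percent",
    "summarize_groups",
]

#: Terrestrial natural abundance of 13C.
P_NATURAL_13C = 0.0107

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MID:
    """Mass-isotopomer distribution of one metabolite.

    fractions[i] is the fractional abundance of the M+i isotopologue;
    the vector has length n_carbons + 1 and sums to 1.
    """

    metabolite: str
    n_carbons: int
    fractions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if self.n_carbons < 1:
            raise ValueError(f"n_carbons must be >= 1, got {self.n_carbons}")
        if f.ndim != 1 or f.size != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite}: expected {self.n_carbons + 1} fractions, "
                f"got shape {f.shape}"
            )
        if np.any(f < -_SUM_TOL):
            raise ValueError(f"{self.metabolite}: negative isotopologue fraction")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite}: fractions sum to {f.sum():.6g}, expected 1"
            )


@dataclass(frozen=True)
class CorrectionMatrix:
    """Natural-abundance convolution matrix for an n-carbon skeleton.

    Entry (i, j) is the probability that a molecule carrying j tracer-labeled
    carbons is observed at mass M+i, i.e. that i-j of its n-j unlabeled
    carbons are naturally 13C. Lower triangular and column stochastic.
    """

    n_carbons: int
    p_natural: float
    matrix: np.ndarray = field(repr=False)


def correction_matrix(n_carbons: int, p_natural: float = P_NATURAL_13C) -> CorrectionMatrix:
    """Build the binomial natural-abundance correction matrix.

    M[i, j] = C(n-j, i-j) * p^(i-j) * (1-p)^(n-i) for i >= j, else 0.
    """
    if n_carbons < 1:
        raise ValueError(f"n_carbons must be >= 1, got {n_carbons}")
    if not 0.0 <= p_natural < 0.5:
        raise ValueError(f"p_natural must be in [0, 0.5), got {p_natural}")
    n = n_carbons
    i, j = np.indices((n + 1, n + 1))
    with np.errstate(invalid="ignore"):
        m = comb(n - j, i - j) * p_natural ** np.maximum(i - j, 0) * (
            1.0 - p_natural
        ) ** np.maximum(n - i, 0)
    m = np.where(i >= j, m, 0.0)
    return CorrectionMatrix(n_carbons=n, p_natural=p_natural, matrix=m)


def convolve_natural_abundance(true_mid: MID, cm: CorrectionMatrix) -> MID:
    """Forward model: distort a tracer-only MID by natural 13C abundance."""
    _check_dims(true_mid, cm)
    measured = cm.matrix @ true_mid.fractions
    return MID(true_mid.metabolite, true_mid.n_carbons, measured / measured.sum())


def correct_mid(measured: MID, cm: CorrectionMatrix) -> MID:
    """Remove natural-abundance contributions from a measured MID.

    Solves ``min ||cm @ x - measured||_2  s.t. x >= 0`` (non-negative least
    squares) and renormalizes x to sum 1. NNLS rather than direct inversion so
    that measurement noise cannot produce negative fractions.
    """
    _check_dims(measured, cm)
    if not np.any(measured.fractions > 0):
        raise ValueError(f"{measured.metabolite}: all-zero measured MID")
    x, _ = nnls(cm.matrix, measured.fractions)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{measured.metabolite}: correction produced a zero vector")
    return MID(measured.metabolite, measured.n_carbons, x / total)


def mcl(mid: MID) -> float:
    """Molecular carbon labeling: weighted average labeled-carbon fraction.

    MCL = sum_i i * f_i / n, in [0, 1]; 0 for unlabeled, 1 for fully labeled.
    """
    i = np.arange(mid.n_carbons + 1)
    return float(np.dot(i, mid.fractions) / mid.n_carbons)


def mx_percent(mid: MID, x: int) -> float:
    """Percentage abundance of the M+x isotopologue (100 * f_x)."""
    if not 0 <= x <= mid.n_carbons:
        raise ValueError(
            f"{mid.metabolite}: M+{x} out of range for {mid.n_carbons} carbons"
        )
    return float(100.0 * mid.fractions[x])


def _check_dims(mid: MID, cm: CorrectionMatrix) -> None:
    if mid.n_carbons != cm.n_carbons:
        raise ValueError(
            f"{mid.metabolite}: MID has {mid.n_carbons} carbons but correction "
            f"matrix is for {cm.n_carbons}"
        )


# ---------------------------------------------------------------------------
# tabular interface


def mids_from_frame(df: pd.DataFrame) -> list[MID]:
    """Parse rows of a tidy MID table (columns m0..mN) into MID objects."""
    out = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        frac = np.array([row[f"m{i}"] for i in range(n + 1)], dtype=float)
        s = frac.sum()
        if s <= 0:
            raise ValueError(f"{row['metabolite']}: all-zero MID row")
        out.append(MID(str(row["metabolite"]), n, frac / s))
    return out


def correct_frame(df: pd.DataFrame, p_natural: float = P_NATURAL_13C) -> pd.DataFrame:
    """Natural-abundance-correct every row of a tidy MID table.

    Expects columns (sample_id, genotype, region, substrate, metabolite,
    n_carbons, m0..mN); returns the same layout with corrected fractions plus
    an ``mcl`` column.
    """
    cms: dict[int, CorrectionMatrix] = {}
    rows = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        cm = cms.setdefault(n, correction_matrix(n, p_natural))
        frac = np.array([row[f"m{i}"] for i in range(n + 1)], dtype=float)
        measured = MID(str(row["metabolite"]), n, frac / frac.sum())
        corrected = correct_mid(measured, cm)
        new = row.to_dict()
        for i in range(n + 1):
            new[f"m{i}"] = corrected.fractions[i]
        new["mcl"] = mcl(corrected)
        rows.append(new)
    return pd.DataFrame(rows)


def summarize_groups(
    corrected: pd.DataFrame,
    group_col: str = "genotype",
    value_col: str = "mcl",
    by: tuple[str, ...] = ("metabolite", "substrate", "region"),
) -> pd.DataFrame:
    """Per-metabolite group means +/- SD with an unpaired two-group t-test.

    ``corrected`` is a tidy table of corrected MIDs (one row per sample x
    metabolite) carrying the summary value in ``value_col`` (MCL by default;
    pass an M+X column for isotopologue-percentage panels). Exactly two group
    levels are compared, mirroring the 5xFAD-vs-WT comparisons.
    """
    from .stats import t_tests

    by = tuple(c for c in by if c in corrected.columns)
    groups = sorted(corrected[group_col].astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {groups}")
    g1, g2 = groups
    out = []
    for keys, sub in corrected.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        a = sub.loc[sub[group_col].astype(str) == g1, value_col].to_numpy(float)
        b = sub.loc[sub[group_col].astype(str) == g2, value_col].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"group with <2 replicates for {dict(zip(by, keys))}"
            )
        tres = t_tests(a, b, paired=False)
        rec = dict(zip(by, keys))
        rec.update(
            {
                f"mean_{g1}": a.mean(),
                f"sd_{g1}": a.std(ddof=1),
                f"n_{g1}": len(a),
                f"mean_{g2}": b.mean(),
                f"sd_{g2}": b.std(ddof=1),
                f"n_{g2}": len(b),
                "t": tres.t,
                "df": tres.df,
                "p": tres.p,
            }
        )
        out.append(rec)
    return pd.DataFrame(out)
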