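"""Concurrent-validity statistics.

Agreement between the standard-instrument and sensor-derived frailty
classifications is quantified with Cohen's kappa (chance-corrected
agreement) and Spearman's rho (rank correlation; for paired binary data
rho equals the phi coefficient). A small integer-enumeration routine
reconstructs a 2x2 table from published marginal counts plus a kappa
value, which makes printed summary statistics re-computable when the
underlying participant-level table is not available.

Conventions
-----------
A 2x2 table is stored as counts (a, b, c, d):

    a  both methods positive       b  method 1 only
    c  method 2 only               d  both methods negative

Kappa p-values use the large-sample normal test with the null-hypothesis
standard error of Fleiss, Cohen & Everitt; Spearman p-values use the
t approximation with df = n - 2. Both are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, InsufficientDataError


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 2:
            raise InsufficientDataError("need n >= 2 paired observations")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins1(self) -> tuple[int, int]:
        """(positive, negative) counts for method 1."""
        return (self.a + self.b, self.c + self.d)

    @property
    def margins2(self) -> tuple[int, int]:
        """(positive, negative) counts for method 2."""
        return (self.a + self.c, self.b + self.d)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_margins_and_agreement(
        cls, pos1: int, pos2: int, n: int, both_pos: int
    ) -> "ContingencyTable2x2":
        """Build the table from marginal positives and the count of
        joint positives (the rest follows by subtraction)."""
        a = both_pos
        b = pos1 - a
        c = pos2 - a
        d = n - a - b - c
        return cls(a, b, c, d)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se0: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    df: int
    p: float


@dataclass(frozen=True)
class AgreementReport:
    """Kappa + Spearman summary for one criterion or score."""

    kappa: Optional[float]
    kappa_p: Optional[float]
    rho: Optional[float]
    rho_df: Optional[int]
    rho_p: Optional[float]
    n: int
    degenerate: bool = False


def crosstab(
    labels1: Sequence[Optional[int]], labels2: Sequence[Optional[int]]
) -> ContingencyTable2x2:
    """2x2 cross-tabulation of paired binary labels.

    Pairs with a missing value (None/NaN) on either side are dropped
    (pairwise deletion).
    """
    if len(labels1) != len(labels2):
        raise ValueError("label vectors must have equal length")
    a = b = c = d = 0
    for u, v in zip(labels1, labels2):
        if u is None or v is None:
            continue
        if isinstance(u, float) and np.isnan(u):
            continue
        if isinstance(v, float) and np.isnan(v):
            continue
        u, v = int(u), int(v)
        if u not in (0, 1) or v not in (0, 1):
            raise ValueError(f"labels must be binary, got ({u}, {v})")
        if u and v:
            a += 1
        elif u:
            b += 1
        elif v:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def cohens_kappa_confusion(matrix: np.ndarray) -> KappaResult:
    """Cohen's kappa for a square k x k confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o the
    diagonal mass and expected agreement p_e from the marginal products.
    The p-value tests kappa = 0 with the Fleiss-Cohen-Everitt null SE.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = m.sum()
    if n < 2:
        raise InsufficientDataError("need n >= 2 paired observations")
    p = m / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = np.trace(p)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError(
            "expected agreement is 1 (degenerate marginals); kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    var0 = (p_e + p_e**2 - float(np.sum(row * col * (row + col)))) / (
        n * (1.0 - p_e) ** 2
    )
    se0 = float(np.sqrt(max(var0, 0.0)))
    if se0 == 0.0:
        z = math.copysign(math.inf, kappa) if kappa != 0 else 0.0
        pval = 0.0 if kappa != 0 else 1.0
    else:
        z = kappa / se0
        pval = 2.0 * stats.norm.sf(abs(z))
    return KappaResult(kappa=float(kappa), se0=se0, z=float(z), p=float(pval),
                       n=int(n))


def cohens_kappa(table: ContingencyTable2x2) -> KappaResult:
    """Cohen's kappa and its two-sided null-hypothesis p for a 2x2 table."""
    return cohens_kappa_confusion(table.as_matrix())


def phi(table: ContingencyTable2x2) -> float:
    """Phi coefficient (ad - bc) / sqrt of the margin product.

    Undefined (raises) when any margin is zero. For paired binary data
    phi equals both the Pearson and the Spearman correlation, which
    makes it an exact oracle for :func:`spearman_rho` on 0/1 vectors.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateTableError("zero margin: phi undefined")
    return (a * d - b * c) / np.sqrt(denom)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with mid-rank tie handling.

    Computed as the Pearson correlation of mid-ranks; the two-sided
    p-value uses the t approximation t = rho * sqrt(df / (1 - rho^2))
    with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateTableError("zero variance: Spearman rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2
    rho_clip = min(max(rho, -1.0), 1.0)
    if abs(rho_clip) == 1.0:
        p = 0.0
    else:
        t = rho_clip * np.sqrt(df / (1.0 - rho_clip**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return SpearmanResult(rho=rho, df=df, p=p)


def table_to_binary_vectors(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2x2 table into the paired 0/1 vectors it summarizes."""
    x = np.concatenate(
        [np.ones(table.a + table.b), np.zeros(table.c + table.d)]
    )
    y = np.concatenate(
        [np.ones(table.a), np.zeros(table.b), np.ones(table.c), np.zeros(table.d)]
    )
    return x, y


def agreement_report(
    labels1: Sequence[Optional[int]], labels2: Sequence[Optional[int]]
) -> AgreementReport:
    """Kappa + binary Spearman for paired binary classifications.

    Degenerate tables (uniform marginals on either side) yield a report
    flagged ``degenerate`` with None statistics, mirroring statistical
    software that refuses the computation under perfect or one-sided
    agreement.
    """
    table = crosstab(labels1, labels2)
    try:
        kr = cohens_kappa(table)
        x, y = table_to_binary_vectors(table)
        sr = spearman_rho(x, y)
    except DegenerateTableError:
        return AgreementReport(kappa=None, kappa_p=None, rho=None, rho_df=None,
                               rho_p=None, n=table.n, degenerate=True)
    return AgreementReport(kappa=kr.kappa, kappa_p=kr.p, rho=sr.rho,
                           rho_df=sr.df, rho_p=sr.p, n=table.n)


def reconstruct_table(
    margin1: tuple[int, int],
    margin2: tuple[int, int],
    kappa_target: float,
    tol: float = 0.005,
) -> ContingencyTable2x2:
    """Recover the unique 2x2 table matching marginals and a kappa value.

    Enumerates every integer table consistent with both (positive,
    negative) margins and returns the one whose kappa is closest to
    ``kappa_target``. Raises if no candidate comes within ``tol``
    (default matches 3-decimal rounding) or if two candidates tie
    within it — the published statistics then under-determine the table.
    """
    pos1, neg1 = margin1
    pos2, neg2 = margin2
    n = pos1 + neg1
    if pos2 + neg2 != n:
        raise ValueError("margins must sum to the same n")
    candidates: list[tuple[float, ContingencyTable2x2]] = []
    for a in range(max(0, pos1 + pos2 - n), min(pos1, pos2) + 1):
        table = ContingencyTable2x2(a, pos1 - a, pos2 - a, n - pos1 - pos2 + a)
        try:
            k = cohens_kappa(table).kappa
        except DegenerateTableError:
            continue
        candidates.append((abs(k - kappa_target), table))
    if not candidates:
        raise ValueError("no feasible non-degenerate table for these margins")
    candidates.sort(key=lambda t: t[0])
    best_dev, best = candidates[0]
    if best_dev > tol:
        raise ValueError(
            f"closest feasible kappa deviates by {best_dev:.4f} > tol {tol}"
        )
    within = [t for dev, t in candidates if dev <= tol]
    if len(within) > 1:
        raise ValueError(
            f"ambiguous reconstruction: {len(within)} tables within tol {tol}: "
            + ", ".join(f"({t.a},{t.b},{t.c},{t.d})" for t in within)
        )
    return best


def stratified_agreement(
    labels1: Sequence[Optional[int]],
    labels2: Sequence[Optional[int]],
    strata: Sequence[str],
) -> dict[str, AgreementReport]:
    """Per-stratum agreement reports (e.g. by sex or age group).

    Strata with fewer than 2 complete pairs are skipped.
    """
    if not (len(labels1) == len(labels2) == len(strata)):
        raise ValueError("labels and strata must have equal length")
    out: dict[str, AgreementReport] = {}
    order = sorted(set(strata), key=str)
    for s in order:
        idx = [i for i, g in enumerate(strata) if g == s]
        l1 = [labels1[i] for i in idx]
        l2 = [labels2[i] for i in idx]
        complete = sum(
            1 for u, v in zip(l1, l2) if u is not None and v is not None
        )
        if complete < 2:
            continue
        out[s] = agreement_report(l1, l2)
    return out


def expected_agreement_hypergeometric(table: ContingencyTable2x2) -> float:
    """Chance agreement by brute force: expectation of the observed
    agreement over all tables with the same margins, weighted by the
    hypergeometric distribution of the (1,1) cell.

    This is an independent route to Cohen's p_e used to validate the
    closed-form marginal-product formula on small tables.
    """
    pos1, _ = table.margins1
    pos2, _ = table.margins2
    n = table.n
    lo = max(0, pos1 + pos2 - n)
    hi = min(pos1, pos2)
    exp_po = 0.0
    for a in itertools.chain(range(lo, hi + 1)):
        w = stats.hypergeom.pmf(a, n, pos1, pos2)
        d = n - pos1 - pos2 + a
        exp_po += w * (a + d) / n
    return float(exp_po)
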