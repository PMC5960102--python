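"""Tajima's relative rate test on ingroup/ingroup/outgroup protein alignments.

For two ingroup lineages A and B and an outgroup O, a column supports a
substitution unique to A when B and O share a residue that A lacks
(``mA``), and symmetrically for B (``mB``).  Under equal rates on the two
ingroup branches, mA and mB have equal expectation and

    chi2 = (mA - mB)^2 / (mA + mB)

is asymptotically chi-squared with one degree of freedom.  The test uses
only these counts — no substitution model or branch-length estimation —
which makes it robust for deep protein comparisons where synonymous
divergence has saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS + GAP + "X")


@dataclass(frozen=True)
class TripleAlignment:
    """Aligned (ingroup A, ingroup B, outgroup O) protein sequences."""

    ortholog_id: str
    a: str
    b: str
    o: str
    masked: bool = False
    column_map: tuple = None  # original column indices after masking

    def __post_init__(self):
        if not (len(self.a) == len(self.b) == len(self.o)):
            raise ValueError(f"{self.ortholog_id}: unequal sequence lengths")
        if len(self.a) == 0:
            raise ValueError(f"{self.ortholog_id}: empty alignment")
        bad = (set(self.a) | set(self.b) | set(self.o)) - _VALID
        if bad:
            raise ValueError(f"{self.ortholog_id}: invalid residues {sorted(bad)}")

    def __len__(self):
        return len(self.a)


@dataclass(frozen=True)
class RateTestResult:
    """Unique-substitution counts and the one-degree chi-squared test."""

    mA: int
    mB: int
    chi2: float
    p: float | None  # None when mA + mB == 0 (test undefined)
    n_used: int
    masked: bool = False
    ortholog_id: str = ""

    @property
    def defined(self) -> bool:
        return self.p is not None


def mask_alignment(
    aln: TripleAlignment,
    max_gap_fraction: float = 0.0,
    window: int = 10,
    min_identity: float = 0.5,
) -> TripleAlignment:
    """Conservation-filter stand-in for divergent-region masking.

    Removes every column containing a gap (when ``max_gap_fraction`` is 0;
    more tolerant settings keep columns whose gap fraction does not exceed
    it) and then every column inside a sliding window of ``window`` columns
    whose mean pairwise identity falls below ``min_identity``.  This is a
    deliberately simple, documented filter — not byte-compatible with
    block-based masking programs; pre-masked alignments can be supplied
    instead.
    """
    if not 0 <= max_gap_fraction <= 1 or not 0 <= min_identity <= 1:
        raise ValueError("thresholds must be in [0, 1]")
    cols = np.array([list(aln.a), list(aln.b), list(aln.o)])
    gap_frac = (cols == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    # mean pairwise identity per column over the three sequence pairs
    ident = (
        (cols[0] == cols[1]).astype(float)
        + (cols[0] == cols[2])
        + (cols[1] == cols[2])
    ) / 3.0
    n = len(aln)
    w = min(window, n)
    if w >= 1:
        csum = np.concatenate([[0.0], np.cumsum(ident)])
        drop = np.zeros(n, dtype=bool)
        for start in range(0, n - w + 1):
            if (csum[start + w] - csum[start]) / w < min_identity:
                drop[start : start + w] = True
        keep &= ~drop
    idx = np.flatnonzero(keep)
    join = lambda row: "".join(row[idx]) if idx.size else ""
    if idx.size == 0:
        # fully masked: keep a placeholder column so the type stays valid,
        # but report zero usable columns downstream via column_map=()
        return TripleAlignment(
            aln.ortholog_id, GAP, GAP, GAP, masked=True, column_map=()
        )
    return TripleAlignment(
        aln.ortholog_id,
        join(cols[0]),
        join(cols[1]),
        join(cols[2]),
        masked=True,
        column_map=tuple(int(i) for i in idx),
    )


def tajima_counts(aln: TripleAlignment) -> tuple[int, int]:
    """Count columns with a substitution unique to A (mA) or to B (mB).

    Columns containing a gap in any of the three sequences are skipped
    (conservative); columns where all three differ, or where the outgroup
    is the odd one out, are uninformative for the two ingroup branches and
    are ignored by construction.
    """
    a = np.frombuffer(aln.a.encode(), dtype="S1")
    b = np.frombuffer(aln.b.encode(), dtype="S1")
    o = np.frombuffer(aln.o.encode(), dtype="S1")
    gap = GAP.encode()
    ok = (a != gap) & (b != gap) & (o != gap)
    mA = int(np.sum(ok & (b == o) & (a != b)))
    mB = int(np.sum(ok & (a == o) & (b != a)))
    return mA, mB


def tajima_test(mA: int, mB: int, *, masked: bool = False, ortholog_id: str = "",
                n_used: int | None = None) -> RateTestResult:
    """One-degree chi-squared test of mA = mB.

    With ``mA + mB == 0`` the test is undefined and ``p`` is reported as
    ``None`` rather than silently 1.
    """
    if mA < 0 or mB < 0:
        raise ValueError("substitution counts must be non-negative")
    total = mA + mB
    if total == 0:
        return RateTestResult(mA, mB, 0.0, None, n_used or 0, masked, ortholog_id)
    chi2 = (mA - mB) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(mA, mB, float(chi2), max(p, np.nextafter(0, 1)),
                          n_used if n_used is not None else total, masked, ortholog_id)


def tajima_test_alignment(aln: TripleAlignment) -> RateTestResult:
    """Convenience: counts plus test for a single triple alignment."""
    if aln.column_map == ():
        return RateTestResult(0, 0, 0.0, None, 0, aln.masked, aln.ortholog_id)
    mA, mB = tajima_counts(aln)
    return tajima_test(mA, mB, masked=aln.masked, ortholog_id=aln.ortholog_id,
                       n_used=len(aln))


def concatenated_test(alignments) -> RateTestResult:
    """Single test on counts summed over a set of same-role alignments.

    All triples must share the same (A, B, O) species roles; summing the
    per-alignment unique-substitution counts is equivalent to testing the
    concatenated alignment and gains power with every added gene.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("empty alignment set")
    masked_flags = {a.masked for a in alignments}
    if len(masked_flags) > 1:
        raise ValueError("mixed masked and unmasked alignments")
    tot_a = tot_b = n_cols = 0
    for aln in alignments:
        if aln.column_map == ():
            continue
        mA, mB = tajima_counts(aln)
        tot_a += mA
        tot_b += mB
        n_cols += len(aln)
    return tajima_test(tot_a, tot_b, masked=masked_flags.pop(),
                       ortholog_id="<concatenated>", n_used=n_cols)


@dataclass(frozen=True)
class RateSummary:
    n_significant: int
    n_faster_a: int      # significant with mA > mB
    n_faster_b: int      # significant with mB > mA
    n_tested: int
    n_undefined: int
    alpha: float
    correction: str


def rate_test_summary(results, alpha: float = 0.05, correction: str = "fdr_bh") -> RateSummary:
    """Count genes with significantly unequal rates, split by lineage.

    P-values are adjusted by ``correction`` (any statsmodels multipletests
    method, or ``"none"`` for raw alpha) before counting; genes whose test
    is undefined (no informative columns) are excluded and tallied.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    results = list(results)
    defined = [r for r in results if r.defined]
    n_undef = len(results) - len(defined)
    if not defined:
        return RateSummary(0, 0, 0, 0, n_undef, alpha, correction)
    pvals = np.array([r.p for r in defined])
    if correction == "none":
        sig = pvals < alpha
    else:
        sig = multipletests(pvals, alpha=alpha, method=correction)[0]
    fa = sum(1 for r, s in zip(defined, sig) if s and r.mA > r.mB)
    fb = sum(1 for r, s in zip(defined, sig) if s and r.mB > r.mA)
    return RateSummary(int(sig.sum()), fa, fb, len(defined), n_undef, alpha, correction)
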