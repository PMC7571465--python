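"""Sliding-window bin-marker genotyping for recombinant inbred lines.

Raw per-line SNP calls from a biparental RIL cross are noisy: low coverage
miscalls heterozygotes, sequencing errors flip alleles, and only SNPs where
the two parents are homozygous for different alleles (the aa x bb pattern)
are informative.  This module turns such calls into *bin markers*:

1. keep aa x bb SNPs and re-code RIL calls onto the parental basis
   (:func:`select_aaxbb`);
2. blank calls below a read-depth floor (:func:`apply_depth_filter`);
3. drop lines with an excess of heterozygous calls, which in a selfed RIL
   population indicates contamination (:func:`filter_lines`);
4. smooth each line with a 15-SNP sliding window -- a window is typed aa
   (or bb) when more than 11 of its SNPs are aa (or bb), otherwise ab
   (:func:`call_line_genotypes`);
5. merge adjacent SNPs with identical genotype vectors across all lines
   into one bin marker (:func:`merge_into_bins`);
6. discard short bins and bins showing segregation distortion under the
   1:1 chi-square test (:func:`filter_bins`).

Genotypes are coded ``0`` (aa, parent-1 homozygote), ``1`` (ab), ``2``
(bb, parent-2 homozygote) and ``-1`` (missing) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

#: on-disk single-character codes, index by genotype value (-1 wraps to '-')
GENOTYPE_CHARS = np.array(["A", "H", "B", "-"])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SNPCallSet:
    """Per-line SNP calls with read depths, plus the two parental calls.

    Parameters
    ----------
    snps
        One row per SNP with columns ``chrom`` (int), ``pos`` (1-based bp,
        strictly increasing within a chromosome), ``p1`` and ``p2``
        (parental genotype codes).  Before :func:`select_aaxbb` the codes
        are in REF/ALT allele space; afterwards parent 1 is ``aa`` and
        parent 2 is ``bb`` by construction.
    calls
        ``(n_lines, n_snps)`` int8 matrix of genotype codes.
    depths
        Matching read-depth matrix, or ``None`` when depths are unknown.
    line_ids
        Sample names, one per row of ``calls``.
    recoded
        True once calls are on the parental (aa/ab/bb) basis.
    """

    snps: pd.DataFrame
    calls: np.ndarray
    depths: np.ndarray | None
    line_ids: list[str]
    recoded: bool = False

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        for chrom, sub in self.snps.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_snps(self, mask: np.ndarray) -> "SNPCallSet":
        """Subset SNPs by boolean mask or integer index, preserving order."""
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return replace(
            self,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            depths=None if self.depths is None else self.depths[:, idx],
        )

    def take_lines(self, mask: np.ndarray) -> "SNPCallSet":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return replace(
            self,
            calls=self.calls[idx],
            depths=None if self.depths is None else self.depths[idx],
            line_ids=[self.line_ids[i] for i in idx],
        )

    def chromosomes(self) -> list[int]:
        return list(pd.unique(self.snps["chrom"]))

    def chrom_index(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(self.snps["chrom"].to_numpy() == chrom)


@dataclass
class GenotyperParams:
    """Tuning knobs of the genotyping pipeline (defaults follow the method)."""

    window_size: int = 15
    window_threshold: int = 11          # strict: count must exceed this
    min_depth: int = 4
    min_bin_length: int = 10_000        # bp; strict "longer than"
    distortion_alpha: float = 0.01
    max_abnormal_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not self.window_threshold < self.window_size:
            raise ValueError("window_threshold must be smaller than window_size")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.distortion_alpha < 1:
            raise ValueError("distortion_alpha must lie in (0, 1)")


@dataclass
class BinMarker:
    """A maximal run of adjacent SNPs sharing one genotype vector."""

    id: str
    chromosome: int
    start_bp: int
    end_bp: int
    genotypes: np.ndarray       # int8 per line
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"bin {self.id}: end_bp < start_bp")

    @property
    def span_bp(self) -> int:
        """Inclusive physical span in bp."""
        return self.end_bp - self.start_bp + 1


@dataclass
class BinSet:
    """Ordered collection of bin markers for one population."""

    bins: list[BinMarker]
    line_ids: list[str]

    def __len__(self) -> int:
        return len(self.bins)

    def matrix(self) -> np.ndarray:
        """Stack genotype vectors into an ``(n_lines, n_bins)`` matrix."""
        if not self.bins:
            return np.empty((len(self.line_ids), 0), dtype=np.int8)
        return np.stack([b.genotypes for b in self.bins], axis=1)

    def frame(self) -> pd.DataFrame:
        """Bin metadata table (id, chrom, start/end bp, n_snps)."""
        return pd.DataFrame(
            {
                "id": [b.id for b in self.bins],
                "chrom": [b.chromosome for b in self.bins],
                "start_bp": [b.start_bp for b in self.bins],
                "end_bp": [b.end_bp for b in self.bins],
                "n_snps": [b.n_snps for b in self.bins],
            }
        )

    def for_chrom(self, chrom: int) -> "BinSet":
        return BinSet([b for b in self.bins if b.chromosome == chrom], self.line_ids)


@dataclass
class FilterReport:
    """Machine-readable account of what a filtering step removed and why."""

    stage: str
    n_in: int
    n_kept: int
    removals: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + len(self.removals):
            raise ValueError(
                f"{self.stage}: {self.n_in} in != {self.n_kept} kept "
                f"+ {len(self.removals)} removed"
            )


# ---------------------------------------------------------------------------
# SNP-level filters
# ---------------------------------------------------------------------------

def select_aaxbb(callset: SNPCallSet) -> tuple[SNPCallSet, FilterReport]:
    """Keep SNPs with the aa x bb parental pattern and re-code RIL calls.

    A SNP is informative in a biparental RIL cross only when both parents
    are homozygous for different alleles.  Retained calls are re-coded so
    that ``aa`` means "parent-1-like" regardless of which parent carried
    the reference allele.  Dropped SNPs are itemised by reason
    (``parent_missing``, ``parent_het``, ``monomorphic``).
    """
    p1 = callset.snps["p1"].to_numpy()
    p2 = callset.snps["p2"].to_numpy()

    missing = (p1 == MISSING) | (p2 == MISSING)
    het = ~missing & ((p1 == AB) | (p2 == AB))
    mono = ~missing & ~het & (p1 == p2)
    keep = ~missing & ~het & ~mono

    reasons = np.where(missing, "parent_missing", np.where(het, "parent_het", "monomorphic"))
    removals = pd.DataFrame(
        {
            "chrom": callset.snps["chrom"].to_numpy()[~keep],
            "pos": callset.snps["pos"].to_numpy()[~keep],
            "reason": reasons[~keep],
        }
    )
    out = callset.take_snps(keep)

    # orient onto the parental basis: flip hom codes where parent 1 carried ALT
    flip = out.snps["p1"].to_numpy() == BB
    calls = out.calls.copy()
    col = calls[:, flip]
    col[col == AA] = 3
    col[col == BB] = AA
    col[col == 3] = BB
    calls[:, flip] = col
    snps = out.snps.copy()
    snps.loc[:, "p1"] = AA
    snps.loc[:, "p2"] = BB
    out = replace(out, snps=snps, calls=calls, recoded=True)

    report = FilterReport("select_aaxbb", callset.n_snps, out.n_snps, removals)
    logger.info("select_aaxbb: kept %d of %d SNPs", out.n_snps, callset.n_snps)
    return out, report


def apply_depth_filter(callset: SNPCallSet, min_depth: int) -> tuple[SNPCallSet, FilterReport]:
    """Blank calls with read depth below ``min_depth``; drop all-missing SNPs.

    The boundary is strict on the low side: depth 4 survives a floor of 4.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if min_depth == 0 or callset.depths is None:
        return callset, FilterReport("depth_filter", callset.n_snps, callset.n_snps)

    calls = callset.calls.copy()
    calls[callset.depths < min_depth] = MISSING
    keep = (calls != MISSING).any(axis=0)
    removals = pd.DataFrame(
        {
            "chrom": callset.snps["chrom"].to_numpy()[~keep],
            "pos": callset.snps["pos"].to_numpy()[~keep],
            "reason": "all_missing_after_depth_filter",
        }
    )
    out = replace(callset, calls=calls).take_snps(keep)
    return out, FilterReport("depth_filter", callset.n_snps, out.n_snps, removals)


def filter_lines(
    callset: SNPCallSet, max_abnormal_fraction: float = 0.02
) -> tuple[SNPCallSet, FilterReport]:
    """Drop lines whose heterozygous-call fraction exceeds the threshold.

    In an RIL population descended from an aa x bb cross, heterozygous
    calls beyond the residual-heterozygosity expectation are "abnormal";
    a line with more than ``max_abnormal_fraction`` of them (among its
    non-missing calls) is treated as contaminated and removed.
    """
    if not callset.recoded:
        raise ValueError("filter_lines expects calls recoded by select_aaxbb")
    informative = (callset.calls != MISSING).sum(axis=1)
    ab = (callset.calls == AB).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(informative > 0, ab / np.maximum(informative, 1), 0.0)
    keep = frac <= max_abnormal_fraction
    if not keep.any():
        raise ValueError("all lines exceed the abnormal-call threshold")
    removals = pd.DataFrame(
        {
            "line_id": [callset.line_ids[i] for i in np.flatnonzero(~keep)],
            "ab_fraction": frac[~keep],
            "reason": "abnormal_fraction",
        }
    )
    out = callset.take_lines(keep)
    logger.info(
        "filter_lines: kept %d of %d lines (threshold %.3f)",
        out.n_lines, callset.n_lines, max_abnormal_fraction,
    )
    return out, FilterReport("filter_lines", callset.n_lines, out.n_lines, removals)


# ---------------------------------------------------------------------------
# window smoothing
# ---------------------------------------------------------------------------

def type_window(aa_count: int, bb_count: int, threshold: int = 11) -> int:
    """Type one window: aa if ``aa_count > threshold``, bb if ``bb_count >
    threshold``, otherwise ab.  Missing calls count toward neither."""
    if aa_count > threshold:
        return AA
    if bb_count > threshold:
        return BB
    return AB


def call_line_genotypes(callset: SNPCallSet, params: GenotyperParams) -> np.ndarray:
    """Smooth raw calls with a sliding window, per line and chromosome.

    A window of ``window_size`` consecutive SNPs slides one SNP at a time.
    Each window is typed by :func:`type_window`; a SNP takes the type of
    the window centred on it, with the first and last ``window_size // 2``
    SNPs inheriting the nearest full window's type.  Chromosomes shorter
    than the window form a single window.  Returns a complete
    ``(n_lines, n_snps)`` matrix with no missing values.
    """
    w, thr = params.window_size, params.window_threshold
    smoothed = np.empty_like(callset.calls)
    chrom_arr = callset.snps["chrom"].to_numpy()
    for chrom in callset.chromosomes():
        idx = np.flatnonzero(chrom_arr == chrom)
        if idx.size == 0:  # pragma: no cover - groupby never yields empties
            logger.warning("chromosome %s has no SNPs; skipped", chrom)
            continue
        calls = callset.calls[:, idx]
        s = idx.size
        eff_w = min(w, s)
        # window counts via cumulative sums along the SNP axis
        is_aa = (calls == AA).astype(np.int32)
        is_bb = (calls == BB).astype(np.int32)
        caa = np.cumsum(is_aa, axis=1)
        cbb = np.cumsum(is_bb, axis=1)
        caa = np.concatenate([np.zeros((calls.shape[0], 1), np.int32), caa], axis=1)
        cbb = np.concatenate([np.zeros((calls.shape[0], 1), np.int32), cbb], axis=1)
        n_win = s - eff_w + 1
        aa_counts = caa[:, eff_w:] - caa[:, :n_win]
        bb_counts = cbb[:, eff_w:] - cbb[:, :n_win]
        wtypes = np.full(aa_counts.shape, AB, dtype=np.int8)
        wtypes[aa_counts > thr] = AA
        wtypes[bb_counts > thr] = BB
        # centre-SNP assignment with edge fill from the nearest full window
        half = eff_w // 2
        win_for_snp = np.clip(np.arange(s) - half, 0, n_win - 1)
        smoothed[:, idx] = wtypes[:, win_for_snp]
    return smoothed


# ---------------------------------------------------------------------------
# bin merging and bin-level filters
# ---------------------------------------------------------------------------

def merge_into_bins(callset: SNPCallSet, smoothed: np.ndarray | None = None) -> BinSet:
    """Merge adjacent SNPs with identical genotype vectors into bin markers.

    Works per chromosome; a bin spans from its first to its last member
    SNP (1-based inclusive bp).  With ``smoothed=None`` the raw call
    matrix is merged, which on error-free data recovers the true
    recombination-breakpoint structure exactly.
    """
    geno = callset.calls if smoothed is None else smoothed
    bins: list[BinMarker] = []
    chrom_arr = callset.snps["chrom"].to_numpy()
    pos_arr = callset.snps["pos"].to_numpy()
    for chrom in callset.chromosomes():
        idx = np.flatnonzero(chrom_arr == chrom)
        g = geno[:, idx]
        # run starts where the genotype vector differs from its neighbour
        changed = np.any(g[:, 1:] != g[:, :-1], axis=0)
        starts = np.concatenate([[0], np.flatnonzero(changed) + 1])
        ends = np.concatenate([starts[1:] - 1, [idx.size - 1]])
        for k, (a, b) in enumerate(zip(starts, ends)):
            bins.append(
                BinMarker(
                    id=f"bin{chrom:02d}_{k:04d}",
                    chromosome=int(chrom),
                    start_bp=int(pos_arr[idx[a]]),
                    end_bp=int(pos_arr[idx[b]]),
                    genotypes=g[:, a].copy(),
                    n_snps=int(b - a + 1),
                )
            )
    return BinSet(bins, list(callset.line_ids))


def chisq_pvalue(chi2: float, df: int = 1) -> float:
    """Upper-tail chi-square probability."""
    return float(stats.chi2.sf(chi2, df=df))


def segregation_chisq(aa_count: int, bb_count: int) -> tuple[float, float]:
    """1:1 segregation chi-square for the two homozygote classes.

    ``chi2 = (aa - bb)^2 / (aa + bb)`` with an upper-tail p-value at 1 df.
    """
    n = aa_count + bb_count
    if n <= 0:
        raise ValueError("segregation test needs at least one homozygous call")
    chi2 = (aa_count - bb_count) ** 2 / n
    return float(chi2), chisq_pvalue(chi2)


def filter_bins(binset: BinSet, params: GenotyperParams) -> tuple[BinSet, FilterReport]:
    """Drop short bins and bins with distorted 1:1 segregation.

    A bin is kept when its inclusive span exceeds ``min_bin_length`` bp
    ("longer than", strict) and its aa:bb chi-square p-value is at least
    ``distortion_alpha``.  Bins with no homozygous calls are removed as
    uninformative.
    """
    kept: list[BinMarker] = []
    rows = []
    for b in binset.bins:
        if b.span_bp <= params.min_bin_length:
            rows.append((b.id, "too_short", b.span_bp, np.nan))
            continue
        aa = int((b.genotypes == AA).sum())
        bb = int((b.genotypes == BB).sum())
        if aa + bb == 0:
            rows.append((b.id, "no_homozygous_calls", b.span_bp, np.nan))
            continue
        _, p = segregation_chisq(aa, bb)
        if p < params.distortion_alpha:
            rows.append((b.id, "segregation_distortion", b.span_bp, p))
            continue
        kept.append(b)
    removals = pd.DataFrame(rows, columns=["bin_id", "reason", "span_bp", "p_value"])
    out = BinSet(kept, binset.line_ids)
    return out, FilterReport("filter_bins", len(binset), len(out), removals)


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def genotype_pipeline(
    callset: SNPCallSet, params: GenotyperParams | None = None
) -> tuple[BinSet, dict[str, FilterReport]]:
    """Run the full genotyping chain: aa x bb selection, depth floor, line
    filter, window smoothing, bin merging, bin filters.

    Returns the filtered :class:`BinSet` and a report per stage.
    """
    params = params or GenotyperParams()
    reports: dict[str, FilterReport] = {}
    cs, reports["select_aaxbb"] = select_aaxbb(callset)
    cs, reports["depth_filter"] = apply_depth_filter(cs, params.min_depth)
    cs, reports["filter_lines"] = filter_lines(cs, params.max_abnormal_fraction)
    smoothed = call_line_genotypes(cs, params)
    binset = merge_into_bins(cs, smoothed)
    binset, reports["filter_bins"] = filter_bins(binset, params)
    return binset, reports
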