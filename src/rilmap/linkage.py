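"""Genetic linkage-map construction from bin markers.

Markers are grouped by reference chromosome (the linkage groups are preset,
one per chromosome), pairwise recombination fractions are estimated on the
RIL scale and transformed to meiotic fractions with the Haldane–Waddington
relation for selfed RILs, marker order is found by nearest-neighbour tour
construction plus two-opt improvement under the SARF criterion (sum of
adjacent recombination fractions) and polished by rippling a 5-marker
window, and distances come from Kosambi's mapping function.

The observed recombinant fraction ``R`` between two bins in a selfed RIL
population overstates the per-meiosis fraction ``r`` because recombinants
keep accumulating over the selfing generations; at fixation
``R = 2r / (1 + 2r)``, inverted here before applying Kosambi.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype import AA, BB, MISSING, BinSet

logger = logging.getLogger(__name__)

R_MAX = 0.49            # cap for meiotic r when building map distances
MIN_INFORMATIVE = 20    # lines required for an informative pair estimate


# ---------------------------------------------------------------------------
# recombination fractions
# ---------------------------------------------------------------------------

def ril_to_meiotic(R: np.ndarray | float) -> np.ndarray | float:
    """Haldane–Waddington inverse for selfed RILs: ``r = R / (2(1-R))``,
    clipped into [0, 0.5)."""
    R = np.clip(np.asarray(R, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(R >= 1.0, 0.5, R / (2.0 * (1.0 - R)))
    return np.minimum(r, 0.5 - 1e-12)


def meiotic_to_ril(r: np.ndarray | float) -> np.ndarray | float:
    """Forward Haldane–Waddington relation ``R = 2r / (1 + 2r)``."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def estimate_rf(geno_i: np.ndarray, geno_j: np.ndarray) -> tuple[float, float, int]:
    """Recombination fraction and linkage LOD between two bin markers.

    Lines non-missing at both bins are informative.  A pair of opposite
    homozygotes counts as one recombinant line; a homozygote next to a
    heterozygote counts as half, since the het call carries exactly one
    recombinant haplotype — this keeps distances additive across the
    short heterozygous transition zones that window smoothing places at
    crossovers.  Returns the meiotic fraction ``r`` (Haldane–Waddington
    inverse of the observed RIL fraction), the LOD of linkage against
    independence, and the informative-line count.  With fewer than
    ``MIN_INFORMATIVE`` informative lines the pair is uninformative:
    ``(0.5, 0.0, n)``.
    """
    ok = (geno_i != MISSING) & (geno_j != MISSING)
    n = int(ok.sum())
    if n < MIN_INFORMATIVE:
        return 0.5, 0.0, n
    gi, gj = geno_i[ok].astype(int), geno_j[ok].astype(int)
    # genotype codes are aa=0, ab=1, bb=2: |difference|/2 is the
    # recombinant-haplotype weight (0, 0.5 or 1)
    nrec = float(np.abs(gi - gj).sum()) / 2.0
    R = nrec / n
    r = float(ril_to_meiotic(R))
    Rc = min(R, 0.5)     # linkage model constrained to R <= 0.5
    with np.errstate(divide="ignore"):
        ll1 = (nrec * np.log10(Rc) if nrec else 0.0) + (
            (n - nrec) * np.log10(1 - Rc) if nrec < n else 0.0
        )
    lod = max(0.0, float(ll1 - n * np.log10(0.5)))
    return r, lod, n


@dataclass
class RFMatrix:
    """Pairwise meiotic recombination fractions and linkage LODs."""

    r: np.ndarray
    lod: np.ndarray
    n_informative: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.r, self.r.T) or np.any(np.diag(self.r) != 0):
            raise ValueError("r must be symmetric with a zero diagonal")

    @property
    def n(self) -> int:
        return self.r.shape[0]


def rf_matrix(genotypes: np.ndarray) -> RFMatrix:
    """All-pairs :func:`estimate_rf` over the columns of a genotype matrix."""
    m = genotypes.shape[1]
    r = np.zeros((m, m))
    lod = np.zeros((m, m))
    ninf = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            rij, lij, nij = estimate_rf(genotypes[:, i], genotypes[:, j])
            r[i, j] = r[j, i] = rij
            lod[i, j] = lod[j, i] = lij
            ninf[i, j] = ninf[j, i] = nij
    return RFMatrix(r, lod, ninf)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(
    binset: BinSet, lod_threshold: float = 3.0
) -> tuple[dict[int, BinSet], pd.DataFrame]:
    """Split bins into linkage groups by reference chromosome.

    Groups are preset (one per chromosome); within-group connectivity at
    ``lod_threshold`` is checked diagnostically and violations reported,
    never re-assigned.  Returns the groups and a report of unlinked bins.
    """
    groups: dict[int, BinSet] = {}
    rows = []
    for chrom in sorted({b.chromosome for b in binset.bins}):
        sub = binset.for_chrom(chrom)
        groups[chrom] = sub
        if len(sub) < 3:
            logger.warning("chromosome %d has only %d bins", chrom, len(sub))
        if len(sub) < 2:
            continue
        rf = rf_matrix(sub.matrix())
        adj = csr_matrix(rf.lod >= lod_threshold)
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp > 1:
            main = np.bincount(labels).argmax()
            for k in np.flatnonzero(labels != main):
                rows.append((sub.bins[k].id, chrom, "unlinked_at_lod_threshold"))
    report = pd.DataFrame(rows, columns=["bin_id", "chrom", "issue"])
    return groups, report


# ---------------------------------------------------------------------------
# ordering: SARF, nearest neighbour, two-opt, rippling
# ---------------------------------------------------------------------------

def sarf(order: np.ndarray, r: np.ndarray) -> float:
    """Sum of adjacent recombination fractions along an ordering."""
    order = np.asarray(order)
    return float(r[order[:-1], order[1:]].sum())


def order_nn_two_opt(r: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Order markers by nearest-neighbour seeding plus two-opt.

    The tour starts from the pair with the smallest recombination fraction
    (lowest indices on ties) and grows by appending, at whichever path end
    is closer, the nearest unplaced marker.  Two-opt then reverses
    sub-segments until no reversal lowers the SARF.  Fully deterministic;
    ``rng`` is accepted for interface symmetry but unused by the
    deterministic tie rules.
    """
    n = r.shape[0]
    if n < 2:
        return np.arange(n)
    iu = np.triu_indices(n, 1)
    k = int(np.lexsort((iu[1], iu[0], r[iu]))[0])
    path = [int(iu[0][k]), int(iu[1][k])]
    left = set(range(n)) - set(path)
    while left:
        cands = sorted((r[end, m], side, m) for side, end in ((0, path[0]), (1, path[-1])) for m in left)
        _, side, m = cands[0]
        if side == 0:
            path.insert(0, m)
        else:
            path.append(m)
        left.discard(m)
    order = np.array(path)

    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                # reverse order[i..j]; only the boundary edges change
                before = 0.0
                after = 0.0
                if i > 0:
                    before += r[order[i - 1], order[i]]
                    after += r[order[i - 1], order[j]]
                if j < n - 1:
                    before += r[order[j], order[j + 1]]
                    after += r[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def ripple_sarf(order: np.ndarray, r: np.ndarray, window: int = 5) -> np.ndarray:
    """Polish an ordering by exhaustively permuting a sliding window.

    Every contiguous window of ``window`` markers is tested against all
    of its permutations; a permutation is accepted only when it strictly
    lowers the total SARF (the best such permutation per window).  Passes
    repeat until one full sweep changes nothing.
    """
    order = np.asarray(order).copy()
    n = len(order)
    if n <= 2:
        return order
    w = min(window, n)
    perms = list(itertools.permutations(range(w)))
    changed = True
    while changed:
        changed = False
        for s in range(n - w + 1):
            seg = order[s : s + w].copy()
            lo = order[s - 1] if s > 0 else -1
            hi = order[s + w] if s + w < n else -1
            def seg_cost(p: tuple[int, ...]) -> float:
                c = float(r[seg[list(p[:-1])], seg[list(p[1:])]].sum())
                if lo >= 0:
                    c += r[lo, seg[p[0]]]
                if hi >= 0:
                    c += r[seg[p[-1]], hi]
                return c
            base = seg_cost(perms[0])
            best, best_cost = None, base - 1e-12
            for p in perms[1:]:
                c = seg_cost(p)
                if c < best_cost:
                    best, best_cost = p, c
            if best is not None:
                order[s : s + w] = seg[list(best)]
                changed = True
    return order


# ---------------------------------------------------------------------------
# distances and map assembly
# ---------------------------------------------------------------------------

def kosambi_cM(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance ``d = 25 ln((1+2r)/(1-2r))`` in centimorgans."""
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * arr) / (1 - 2 * arr))
    return float(d) if np.isscalar(r) else d


def inverse_kosambi(d: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from Kosambi distance: ``r = tanh(d/50)/2``."""
    r = 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)
    return float(r) if np.isscalar(d) else r


@dataclass
class LinkageGroup:
    """One ordered linkage group with cumulative cM positions."""

    id: str
    chromosome: int
    bin_ids: list[str]
    positions_cM: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bin_ids) != len(self.positions_cM):
            raise ValueError("one position per bin required")
        if len(self.positions_cM) and (
            self.positions_cM[0] != 0 or np.any(np.diff(self.positions_cM) < 0)
        ):
            raise ValueError("positions must start at 0 and be non-decreasing")

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.bin_ids)


@dataclass
class GeneticMap:
    """All linkage groups of one map."""

    groups: list[LinkageGroup]

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for bid, cm, s, e in zip(g.bin_ids, g.positions_cM, g.start_bp, g.end_bp):
                rows.append((bid, g.id, round(float(cm), 4), g.chromosome, int(s), int(e)))
        return pd.DataFrame(rows, columns=["marker", "lg", "cM", "chrom", "start_bp", "end_bp"])


def assemble_group(
    group_id: str, binset: BinSet, order: np.ndarray, r: np.ndarray
) -> LinkageGroup:
    """Cumulative Kosambi positions along an ordering, oriented so the
    first marker's bp position precedes the last's."""
    bins = [binset.bins[i] for i in order]
    if len(bins) > 1 and bins[0].start_bp > bins[-1].start_bp:
        order = order[::-1]
        bins = bins[::-1]
    if len(bins) < 2:
        pos = np.zeros(len(bins))
    else:
        adj = r[order[:-1], order[1:]]
        capped = np.minimum(adj, R_MAX)
        if np.any(adj > R_MAX):
            logger.warning("%s: %d adjacent r capped at %.2f", group_id, int((adj > R_MAX).sum()), R_MAX)
        pos = np.concatenate([[0.0], np.cumsum(kosambi_cM(capped))])
    return LinkageGroup(
        id=group_id,
        chromosome=bins[0].chromosome if bins else -1,
        bin_ids=[b.id for b in bins],
        positions_cM=pos,
        start_bp=np.array([b.start_bp for b in bins]),
        end_bp=np.array([b.end_bp for b in bins]),
    )


def build_map(
    binset: BinSet, rng: np.random.Generator | None = None, ripple_window: int = 5
) -> tuple[GeneticMap, pd.DataFrame]:
    """Full map construction: group, estimate, order, ripple, assemble."""
    groups, link_report = group_markers(binset)
    lgs = []
    for k, chrom in enumerate(sorted(groups), start=1):
        sub = groups[chrom]
        if len(sub) == 0:
            continue
        rf = rf_matrix(sub.matrix())
        order = order_nn_two_opt(rf.r, rng)
        order = ripple_sarf(order, rf.r, ripple_window)
        lgs.append(assemble_group(f"LG{k}", sub, order, rf.r))
    return GeneticMap(lgs), link_report


def map_summary(gmap: GeneticMap, gap_cM: float = 5.0) -> pd.DataFrame:
    """Per-group and overall map statistics.

    Per group: marker count, total cM, average spacing (total over
    count-1), max gap and gaps above ``gap_cM`` and 10 cM.  The overall
    row reports both averaging conventions — total length per marker and
    per interval — since summary tables in the field mix the two.
    """
    rows = []
    for g in gmap.groups:
        gaps = np.diff(g.positions_cM) if g.n_markers > 1 else np.array([])
        rows.append(
            {
                "lg": g.id,
                "n_markers": g.n_markers,
                "length_cM": round(g.length_cM, 2),
                "avg_spacing_cM": round(g.length_cM / (g.n_markers - 1), 2)
                if g.n_markers > 1
                else 0.0,
                "max_gap_cM": round(float(gaps.max()), 2) if gaps.size else 0.0,
                "n_gaps_gt5": int((gaps > gap_cM).sum()),
                "n_gaps_gt10": int((gaps > 10.0).sum()),
            }
        )
    total_len = gmap.total_length_cM
    n_mark = gmap.n_markers
    n_intervals = n_mark - len(gmap.groups)
    rows.append(
        {
            "lg": "Total",
            "n_markers": n_mark,
            "length_cM": round(total_len, 2),
            "avg_spacing_cM": round(total_len / n_mark, 2) if n_mark else 0.0,
            "max_gap_cM": float("nan"),
            "n_gaps_gt5": int(sum(r["n_gaps_gt5"] for r in rows)),
            "n_gaps_gt10": int(sum(r["n_gaps_gt10"] for r in rows)),
        }
    )
    out = pd.DataFrame(rows)
    out["avg_spacing_per_interval_cM"] = [
        round(r["length_cM"] / (r["n_markers"] - 1), 2) if r["n_markers"] > 1 else 0.0
        for r in rows[:-1]
    ] + [round(total_len / n_intervals, 2) if n_intervals else 0.0]
    return out
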