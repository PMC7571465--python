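"""Inclusive composite interval mapping (ICIM) for RIL populations.

The scan follows the two-stage ICIM scheme.  Stage one selects background
cofactors by forward-backward stepwise linear regression of the phenotype
on all bin markers (entry when the partial-F p-value falls below ``pin``,
removal when it rises above ``pout``).  Stage two walks the genetic map in
small steps; at each position the phenotype — adjusted by subtracting all
cofactor contributions except those of the flanking markers of the current
interval, which are released — is fitted as a two-component normal mixture
whose component weights per line are the conditional probabilities of the
two QTL homozygote classes given the nearest informative flanking markers.
The mixture is maximised by EM and compared with a single-normal null:

    LOD = log10( L_QTL / L_null ).

Genome-wide significance comes from a permutation test: the phenotype is
shuffled against the genotypes, the whole scan (including cofactor
selection) is repeated, and the empirical (1 - alpha) quantile of the
per-permutation maximum LOD is the threshold.

Markers are coded +1 (aa), -1 (bb), 0 (ab or missing) in the cofactor
regression; in the mixture the heterozygous and missing calls contribute
through flanking-marker probabilities only.  Recombination between a scan
position and its flanks uses the inverse Kosambi distance transformed to
the RIL scale by the Haldane–Waddington relation, and the RIL chromosome
mosaic is treated as Markov along the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import AA, BB, BinSet
from .linkage import GeneticMap, inverse_kosambi, meiotic_to_ril

LN10 = np.log(10.0)
_EM_MAX_ITER = 50
_EM_TOL = 1e-8


@dataclass
class ScanParams:
    """ICIM scan settings (defaults follow the method's published choices)."""

    step_cM: float = 0.1
    pin: float = 0.001
    pout: float | None = None       # defaults to 2 * pin
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pout is None:
            self.pout = 2 * self.pin
        if not 0 < self.pin < self.pout < 1:
            raise ValueError("need 0 < pin < pout < 1")
        if self.step_cM <= 0:
            raise ValueError("step_cM must be positive")
        if self.n_permutations < 100:
            raise ValueError("use at least 100 permutations")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class QTLResult:
    """One detected QTL, Table-style."""

    trait: str
    name: str
    lg: str
    peak_cM: float
    left_marker: str
    right_marker: str
    phys_start_bp: int
    phys_end_bp: int
    lod: float
    pve: float
    additive: float
    threshold: float
    ci_lo_cM: float     # 1.5-LOD-drop support interval
    ci_hi_cM: float


# ---------------------------------------------------------------------------
# marker coding and map alignment
# ---------------------------------------------------------------------------

def code_markers(genotypes: np.ndarray) -> np.ndarray:
    """aa -> +1, bb -> -1, ab/missing -> 0 (the homozygote midpoint)."""
    x = np.zeros(genotypes.shape, dtype=float)
    x[genotypes == AA] = 1.0
    x[genotypes == BB] = -1.0
    return x


@dataclass
class MapData:
    """Genotypes aligned to map order, with per-group slices."""

    gmap: GeneticMap
    genotypes: np.ndarray               # (n_lines, n_markers) in map order
    marker_ids: list[str]
    lg_slices: dict[str, slice]
    coded: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coded = code_markers(self.genotypes)

    @classmethod
    def from_binset(cls, gmap: GeneticMap, binset: BinSet) -> "MapData":
        col = {b.id: k for k, b in enumerate(binset.bins)}
        mat = binset.matrix()
        ids: list[str] = []
        slices: dict[str, slice] = {}
        cols: list[int] = []
        for g in gmap.groups:
            start = len(ids)
            for bid in g.bin_ids:
                cols.append(col[bid])
                ids.append(bid)
            slices[g.id] = slice(start, len(ids))
        return cls(gmap, mat[:, cols], ids, slices)


# ---------------------------------------------------------------------------
# stepwise cofactor selection
# ---------------------------------------------------------------------------

def stepwise_select(
    X: np.ndarray, y: np.ndarray, pin: float = 0.001, pout: float = 0.002
) -> tuple[list[int], np.ndarray]:
    """Forward-backward stepwise regression over coded markers.

    A marker enters when its partial-F p-value (given the current model)
    is the smallest and below ``pin``; after each entry, any selected
    marker whose drop-one p-value exceeds ``pout`` leaves (largest
    first).  Ties resolve to the lowest marker index.  Returns the
    selected column indices and their coefficients (intercept excluded).
    """
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    selected: list[int] = []
    for _ in range(min(n - 2, m, 50)):
        D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        Q, _ = np.linalg.qr(D)
        yr = y - Q @ (Q.T @ y)
        Xr = X - Q @ (Q.T @ X)
        ssx = np.einsum("ij,ij->j", Xr, Xr)
        ssy = float(yr @ yr)
        dof = n - D.shape[1] - 1
        if dof < 1 or ssy <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ssx > 1e-12 * n, (Xr.T @ yr) ** 2 / (ssx * ssy), 0.0)
        r2[selected] = 0.0
        r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
        F = dof * r2 / (1.0 - r2)
        pvals = stats.f.sf(F, 1, dof)
        j = int(np.argmin(pvals))
        if pvals[j] >= pin:
            break
        selected.append(j)
        # backward sweep
        while len(selected) > 1:
            D = np.column_stack([np.ones(n)] + [X[:, k] for k in selected])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            dof2 = n - D.shape[1]
            s2 = float(resid @ resid) / dof2
            cov = np.linalg.pinv(D.T @ D) * s2
            t = beta[1:] / np.sqrt(np.maximum(np.diag(cov)[1:], 1e-300))
            pv = 2 * stats.t.sf(np.abs(t), dof2)
            worst = int(np.argmax(pv))
            if pv[worst] <= pout:
                break
            selected.pop(worst)
    if not selected:
        return [], np.array([])
    D = np.column_stack([np.ones(n)] + [X[:, k] for k in selected])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return selected, beta[1:]


def _stepwise_many(X: np.ndarray, Y: np.ndarray, pin: float, pout: float):
    """Stepwise selection for many phenotype rows, with a vectorised fast
    path for rows whose best single-marker p-value never reaches ``pin``
    (the common case for permuted phenotypes)."""
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ssy = np.einsum("ij,ij->i", Yc, Yc)
    num = Yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ssx > 1e-12 * n, num**2 / (ssx[None, :] * ssy[:, None]), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    F = (n - 2) * r2 / (1 - r2)
    minp = stats.f.sf(F.max(axis=1) * 1.0, 1, n - 2)  # best marker per row
    out = []
    for i in range(Y.shape[0]):
        if minp[i] >= pin:
            out.append(([], np.array([])))
        else:
            out.append(stepwise_select(X, Y[i], pin, pout))
    return out


# ---------------------------------------------------------------------------
# flanking-marker QTL-genotype probabilities
# ---------------------------------------------------------------------------

class _GroupGrid:
    """Per-group scan grid with per-line class-probability machinery."""

    def __init__(self, cm: np.ndarray, geno: np.ndarray, step: float):
        self.cm = cm
        self.geno = geno
        n, m = geno.shape
        hom = np.isin(geno, (AA, BB))
        idx = np.arange(m)[None, :].repeat(n, axis=0)
        last = np.where(hom, idx, -1)
        self.last_inf = np.maximum.accumulate(last, axis=1)
        nxt = np.where(hom, idx, m)
        self.next_inf = np.minimum.accumulate(nxt[:, ::-1], axis=1)[:, ::-1]
        length = float(cm[-1]) if m else 0.0
        grid = np.round(np.arange(0.0, length + step / 2, step), 10)
        # scan at every marker as well, so marker-coincident positions use
        # the observed genotypes exactly
        self.positions = np.unique(np.concatenate([grid, np.round(cm, 10)]))

    def class_probs(self, pos: float) -> np.ndarray:
        """P(QTL = aa | nearest informative flanking markers) per line."""
        cm, geno = self.cm, self.geno
        m = len(cm)
        k = int(np.searchsorted(cm, pos + 1e-9) - 1)    # marker at pos included
        left = self.last_inf[:, k] if k >= 0 else np.full(geno.shape[0], -1)
        right = self.next_inf[:, min(k + 1, m - 1)] if k + 1 < m else np.full(
            geno.shape[0], m
        )
        # a marker exactly at pos that is informative acts as its own flank
        # (distance 0 makes its class probability 0 or 1)
        n = geno.shape[0]
        p = np.full(n, 0.5)
        has_l = left >= 0
        has_r = right < m
        dL = np.where(has_l, pos - cm[np.clip(left, 0, m - 1)], np.nan)
        dR = np.where(has_r, cm[np.clip(right, 0, m - 1)] - pos, np.nan)
        RL = meiotic_to_ril(inverse_kosambi(np.where(has_l, dL, 0.0)))
        RR = meiotic_to_ril(inverse_kosambi(np.where(has_r, dR, 0.0)))
        gL_aa = geno[np.arange(n), np.clip(left, 0, m - 1)] == AA
        gR_aa = geno[np.arange(n), np.clip(right, 0, m - 1)] == AA

        both = has_l & has_r
        pl = np.where(gL_aa, 1 - RL, RL)
        pr = np.where(gR_aa, 1 - RR, RR)
        ql = np.where(gL_aa, RL, 1 - RL)
        qr = np.where(gR_aa, RR, 1 - RR)
        with np.errstate(invalid="ignore"):
            p = np.where(both, pl * pr / np.maximum(pl * pr + ql * qr, 1e-300), p)
        p = np.where(has_l & ~has_r, pl, p)
        p = np.where(~has_l & has_r, pr, p)
        return p

    def interval_markers(self, pos: float) -> tuple[int, int]:
        """Indices (within the group) of the flanking markers of ``pos``."""
        m = len(self.cm)
        k = int(np.searchsorted(self.cm, pos + 1e-9) - 1)
        return max(k, 0), min(max(k, 0) + 1, m - 1)


# ---------------------------------------------------------------------------
# the EM mixture and the scan
# ---------------------------------------------------------------------------

def _mixture_lod(Y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the two-class normal mixture by EM for each phenotype row.

    ``Y`` is ``(P, n)``; ``p`` the per-line prior probability of class aa.
    Returns per-row ``(lod, mu_aa, mu_bb)``.
    """
    P, n = Y.shape
    mu0 = Y.mean(axis=1, keepdims=True)
    var0 = Y.var(axis=1, keepdims=True)
    var0 = np.maximum(var0, 1e-300)
    ll0 = -0.5 * n * (np.log(2 * np.pi * var0[:, 0]) + 1.0)

    wsum = max(p.sum(), 1e-12)
    vsum = max((1 - p).sum(), 1e-12)
    mu1 = (Y @ p / wsum)[:, None]
    mu2 = (Y @ (1 - p) / vsum)[:, None]
    s2 = np.maximum(var0.copy(), 1e-12)
    pb = p[None, :]
    lod_old = np.full(P, -np.inf)
    ll = np.full(P, -np.inf)
    for _ in range(_EM_MAX_ITER):
        d1 = Y - mu1
        d2 = Y - mu2
        # responsibilities from the common-variance likelihood ratio
        z = (d2**2 - d1**2) / (2 * s2)
        z = np.clip(z, -700, 700)
        w = pb * np.exp(z)
        w = w / (w + (1 - pb))
        sw = w.sum(axis=1, keepdims=True)
        sv = (1 - w).sum(axis=1, keepdims=True)
        mu1 = np.where(sw > 1e-12, (w * Y).sum(axis=1, keepdims=True) / np.maximum(sw, 1e-12), mu0)
        mu2 = np.where(sv > 1e-12, ((1 - w) * Y).sum(axis=1, keepdims=True) / np.maximum(sv, 1e-12), mu0)
        d1 = Y - mu1
        d2 = Y - mu2
        s2 = (w * d1**2 + (1 - w) * d2**2).sum(axis=1, keepdims=True) / n
        s2 = np.maximum(s2, 1e-12 * np.maximum(var0, 1e-12))
        log_comp = np.log(
            pb * np.exp(-0.5 * d1**2 / s2) + (1 - pb) * np.exp(-0.5 * d2**2 / s2)
        )
        ll = (log_comp - 0.5 * np.log(2 * np.pi * s2)).sum(axis=1)
        # converge on the LOD itself: scale- and shift-invariant
        lod_now = (ll - ll0) / LN10
        if np.all(np.abs(lod_now - lod_old) <= _EM_TOL):
            break
        lod_old = lod_now
    lod = np.maximum((ll - ll0) / LN10, 0.0)
    return lod, mu1[:, 0], mu2[:, 0]


def compute_pve(genetic_values: np.ndarray, total_variance: float) -> float:
    """Percent of phenotypic variance explained by per-line genetic values."""
    if total_variance <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return 100.0 * float(np.var(genetic_values)) / total_variance


def adjust_phenotype(
    y: np.ndarray,
    X: np.ndarray,
    selected: list[int],
    coefs: np.ndarray,
    released: set[int],
) -> np.ndarray:
    """Subtract all cofactor contributions except the released ones."""
    y_adj = y.astype(float).copy()
    for j, b in zip(selected, coefs):
        if j not in released:
            y_adj -= b * X[:, j]
    return y_adj


def interval_scan(
    mapdata: MapData,
    Y: np.ndarray,
    params: ScanParams,
    cofactors: list[tuple[list[int], np.ndarray]] | None = None,
    total_variance: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scan every linkage group at ``step_cM`` resolution.

    ``Y`` holds one phenotype per row (permutation replicates scan in one
    call).  Returns the profile of the first row as a tidy frame
    (``lg, cM, lod, additive, pve``) and the ``(P, n_positions)`` LOD
    matrix for all rows.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    P, n = Y.shape
    X = mapdata.coded
    if cofactors is None:
        cofactors = [([], np.array([]))] * P
    base = np.stack(
        [
            Y[i] - sum((b * X[:, j] for j, b in zip(*cofactors[i])), np.zeros(n))
            for i in range(P)
        ]
    )
    if total_variance is None:
        total_variance = Y.var(axis=1)

    rows = []
    lod_cols = []
    for g in mapdata.gmap.groups:
        sl = mapdata.lg_slices[g.id]
        grid = _GroupGrid(g.positions_cM, mapdata.genotypes[:, sl], params.step_cM)
        offset = sl.start
        for pos in grid.positions:
            p = grid.class_probs(float(pos))
            kL, kR = grid.interval_markers(float(pos))
            released_global = {offset + kL, offset + kR}
            Yp = base.copy()
            for i, (sel, b) in enumerate(cofactors):
                for j, bj in zip(sel, b):
                    if j in released_global:
                        Yp[i] += bj * X[:, j]
            lod, mu1, mu2 = _mixture_lod(Yp, p)
            lod_cols.append(lod)
            gvals = p * mu1[0] + (1 - p) * mu2[0]
            rows.append(
                (
                    g.id,
                    float(pos),
                    float(lod[0]),
                    float((mu1[0] - mu2[0]) / 2.0),
                    100.0 * float(np.var(gvals)) / max(float(total_variance[0]), 1e-300),
                )
            )
    profile = pd.DataFrame(rows, columns=["lg", "cM", "lod", "additive", "pve"])
    lod_matrix = np.stack(lod_cols, axis=1) if lod_cols else np.zeros((P, 0))
    return profile, lod_matrix


def permutation_threshold(
    mapdata: MapData,
    y: np.ndarray,
    params: ScanParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide LOD cutoff from permutations of the phenotype.

    The phenotype is shuffled ``n_permutations`` times; each permutation
    re-runs cofactor selection and the full scan.  The cutoff is the
    ``ceil((1 - alpha) * N)``-th smallest of the per-permutation maximum
    LODs, which under exchangeability gives an exceedance probability of
    about ``alpha`` for a fresh null scan.
    """
    rng = rng or np.random.default_rng(params.seed)
    N = params.n_permutations
    perms = np.stack([rng.permutation(len(y)) for _ in range(N)])
    Y = np.asarray(y, dtype=float)[perms]
    cof = _stepwise_many(mapdata.coded, Y, params.pin, params.pout)
    _, lod_matrix = interval_scan(mapdata, Y, params, cofactors=cof)
    max_lod = np.sort(lod_matrix.max(axis=1))
    k = int(np.ceil((1 - params.alpha) * N)) - 1
    return float(max_lod[np.clip(k, 0, N - 1)])


def call_qtl(
    profile: pd.DataFrame,
    threshold: float,
    mapdata: MapData,
    trait: str = "trait",
) -> list[QTLResult]:
    """Collapse contiguous supra-threshold runs into QTL calls.

    Each run reports its maximum-LOD position, the nearest mapped bins on
    either side of the peak (with their physical bp span) and a 1.5-LOD
    support interval.  An empty list means nothing cleared the threshold.
    """
    results: list[QTLResult] = []
    count = 0
    for g in mapdata.gmap.groups:
        sub = profile[profile["lg"] == g.id].reset_index(drop=True)
        above = sub["lod"].to_numpy() >= threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            run = sub.iloc[s:e]
            peak = run.iloc[int(np.argmax(run["lod"].to_numpy()))]
            pos = float(peak["cM"])
            cm = g.positions_cM
            kL = int(np.clip(np.searchsorted(cm, pos + 1e-9) - 1, 0, len(cm) - 1))
            kR = min(kL + 1, len(cm) - 1)
            # 1.5-LOD drop interval within this group's profile
            lods = sub["lod"].to_numpy()
            pk = int(run.index[int(np.argmax(run["lod"].to_numpy()))])
            drop = float(peak["lod"]) - 1.5
            lo = pk
            while lo > 0 and lods[lo - 1] >= drop:
                lo -= 1
            hi = pk
            while hi < len(lods) - 1 and lods[hi + 1] >= drop:
                hi += 1
            count += 1
            results.append(
                QTLResult(
                    trait=trait,
                    name=f"q{trait}.{count}",
                    lg=g.id,
                    peak_cM=pos,
                    left_marker=g.bin_ids[kL],
                    right_marker=g.bin_ids[kR],
                    phys_start_bp=int(g.start_bp[kL]),
                    phys_end_bp=int(g.end_bp[kR]),
                    lod=float(peak["lod"]),
                    pve=float(peak["pve"]),
                    additive=float(peak["additive"]),
                    threshold=threshold,
                    ci_lo_cM=float(sub["cM"].iloc[lo]),
                    ci_hi_cM=float(sub["cM"].iloc[hi]),
                )
            )
    return results


def scan_trait(
    gmap: GeneticMap,
    binset: BinSet,
    phenotype: np.ndarray,
    params: ScanParams | None = None,
    trait: str = "trait",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float, list[QTLResult]]:
    """Complete ICIM analysis of one trait: cofactors, scan, permutation
    threshold, QTL calls."""
    params = params or ScanParams()
    rng = rng or np.random.default_rng(params.seed)
    mapdata = MapData.from_binset(gmap, binset)
    y = np.asarray(phenotype, dtype=float)
    sel, coefs = stepwise_select(mapdata.coded, y, params.pin, params.pout)
    profile, _ = interval_scan(
        mapdata, y[None, :], params, cofactors=[(sel, coefs)],
        total_variance=np.array([y.var()]),
    )
    threshold = permutation_threshold(mapdata, y, params, rng)
    return profile, threshold, call_qtl(profile, threshold, mapdata, trait)
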