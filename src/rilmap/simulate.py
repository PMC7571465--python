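"""Synthetic RIL populations, observed SNP calls, phenotypes and leaf shapes.

The generator emulates the data a genome-sequenced recombinant-inbred-line
(RIL) study produces, with full ground truth attached:

* an F1 between two inbred parents advanced by strict single seed descent
  (one selfed plant per line per generation) to, by default, the eighth
  generation, on 11 chromosomes — crossovers are Poisson with no
  interference (Haldane model);
* SNP calls observed through a read-depth/error model: depths are Poisson,
  each read independently miscalls its allele, and a heterozygote is only
  called when both alleles are actually seen, so low coverage collapses
  het calls to homozygotes;
* line-level contamination: a chosen fraction of lines gets an inflated
  heterozygous-call rate, the realistic trigger for the "abnormal line"
  filter downstream;
* quantitative phenotypes driven by one or more additive QTL with a
  target percentage of variance explained (PVE), plus Gaussian noise;
* parametric leaflet outlines (ovate, lobed, or indented) with exact
  analytic areas and landmark annotations, for the morphometrics stage.

All randomness flows through a single :class:`numpy.random.Generator`;
identical configurations and seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import AA, AB, BB, MISSING, SNPCallSet

Mosaic = tuple[np.ndarray, np.ndarray]
"""A parental-origin mosaic along one chromosome: ``(ends_cM, origins)``.

Segment ``i`` covers the half-open genetic interval
``(ends_cM[i-1], ends_cM[i]]`` (the first starts at 0) and carries origin
``0`` (parent 1) or ``1`` (parent 2).  ``ends_cM`` is strictly increasing
and terminates at the chromosome length.
"""

TRAITS = ("NA", "R", "Q")

#: trait baselines added to the genetic + noise signal (apex count; percent)
TRAIT_BASELINES = {"NA": 6.0, "R": 75.0, "Q": 70.0}

#: residual noise SD used for a trait with no QTL acting on it
NULL_NOISE_SD = {"NA": 1.5, "R": 8.0, "Q": 8.0}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class QTLSpec:
    """One additive QTL: where it sits, how strong it is, which trait."""

    chromosome: int
    position_cM: float
    additive_effect: float
    target_pve: float
    trait: str = "R"

    def __post_init__(self) -> None:
        if not 0 < self.target_pve < 100:
            raise ValueError("target_pve must lie strictly between 0 and 100")
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")
        if self.position_cM < 0:
            raise ValueError("position_cM must be non-negative")


@dataclass
class SimConfig:
    """Study design of the simulated population.

    The defaults mirror the mapping study the pipeline targets: ~190 lines
    on 11 chromosomes advanced to the eighth selfed generation, observed at
    moderate depth with a small per-read error rate, with a handful of
    contaminated lines.
    """

    n_chromosomes: int = 11
    chrom_lengths_cM: list[float] = field(default_factory=lambda: [96.0] * 11)
    chrom_lengths_bp: list[int] = field(default_factory=lambda: [30_000_000] * 11)
    n_snps_per_chrom: int = 2000
    n_lines: int = 190
    n_generations: int = 8
    mean_depth: float = 20.0
    error_rate: float = 0.002
    missing_rate: float = 0.02
    contaminated_line_fraction: float = 15 / 190
    contamination_het_rate: float = 0.05
    #: SNP placement irregularity: 0 = regular grid, 0.45 = nearly uniform
    #: jitter around it.  Regular grids keep adjacent gaps identifiable,
    #: which ordering benchmarks rely on; real SNP maps are irregular.
    marker_jitter: float = 0.45
    qtl_specs: list[QTLSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_snps_per_chrom, self.n_lines) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_generations < 2:
            raise ValueError("need at least two generations (F1 plus one selfing)")
        if len(self.chrom_lengths_cM) != self.n_chromosomes or len(
            self.chrom_lengths_bp
        ) != self.n_chromosomes:
            raise ValueError("per-chromosome length lists must match n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths_cM) or any(
            l <= 0 for l in self.chrom_lengths_bp
        ):
            raise ValueError("chromosome lengths must be positive")
        for rate in (self.error_rate, self.missing_rate, self.contaminated_line_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.marker_jitter < 0.5:
            raise ValueError("marker_jitter must lie in [0, 0.5)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        for q in self.qtl_specs:
            if q.chromosome >= self.n_chromosomes:
                raise ValueError(f"QTL chromosome {q.chromosome} out of range")
            if q.position_cM > self.chrom_lengths_cM[q.chromosome]:
                raise ValueError("QTL position beyond chromosome end")


# ---------------------------------------------------------------------------
# meiosis and breeding
# ---------------------------------------------------------------------------

def _mosaic_at(mosaic: Mosaic, positions: np.ndarray) -> np.ndarray:
    """Parental origin of each genetic position (cM) under a mosaic."""
    ends, origins = mosaic
    idx = np.searchsorted(ends, positions, side="left")
    return origins[np.minimum(idx, len(origins) - 1)]

def _extract(mosaic: Mosaic, a: float, b: float) -> tuple[list[float], list[int]]:
    """Segments of ``mosaic`` restricted to the interval ``(a, b]``."""
    ends, origins = mosaic
    i = int(np.searchsorted(ends, a, side="right"))
    out_e: list[float] = []
    out_o: list[int] = []
    while i < len(ends):
        out_e.append(min(float(ends[i]), b))
        out_o.append(int(origins[i]))
        if ends[i] >= b:
            break
        i += 1
    return out_e, out_o


def simulate_meiosis(
    parent_haplotypes: tuple[Mosaic, Mosaic], chrom_length_cM: float, rng: np.random.Generator
) -> Mosaic:
    """One gamete from a pair of haplotype mosaics.

    The crossover count is Poisson with mean ``chrom_length_cM / 100``
    (no interference); crossover positions are uniform on the chromosome.
    The gamete alternates between the two input haplotypes at each
    crossover, starting from a uniformly chosen one.
    """
    if chrom_length_cM <= 0:
        raise ValueError("chromosome length must be positive")
    h = parent_haplotypes
    k = int(rng.poisson(chrom_length_cM / 100.0))
    cur = int(rng.integers(2))
    if k == 0:
        ends, origins = h[cur]
        return ends.copy(), origins.copy()
    xovers = np.sort(rng.uniform(0.0, chrom_length_cM, size=k))
    bounds = np.concatenate([[0.0], xovers, [chrom_length_cM]])
    ends: list[float] = []
    origins: list[int] = []
    for j in range(len(bounds) - 1):
        a, b = float(bounds[j]), float(bounds[j + 1])
        if b <= a:
            cur ^= 1
            continue
        e, o = _extract(h[cur], a, b)
        for ee, oo in zip(e, o):
            if origins and origins[-1] == oo:
                ends[-1] = ee        # merge contiguous same-origin segments
            else:
                ends.append(ee)
                origins.append(oo)
        cur ^= 1
    ends[-1] = chrom_length_cM
    return np.asarray(ends), np.asarray(origins, dtype=np.int8)


@dataclass
class TruePopulation:
    """Ground truth for a simulated RIL population.

    ``haplotypes[line][chrom]`` is the pair of parental-origin mosaics of
    that line; ``markers`` holds per-SNP ``chrom``, ``pos_bp`` and ``cM``;
    ``genotypes`` is the ``(n_lines, n_snps)`` matrix of true calls.
    """

    config: SimConfig
    markers: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: list[list[tuple[Mosaic, Mosaic]]]
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def genotypes_at(self, chromosome: int, position_cM: float) -> np.ndarray:
        """True genotype of every line at an arbitrary genetic position."""
        out = np.empty(self.n_lines, dtype=np.int8)
        pos = np.array([position_cM])
        for i, line in enumerate(self.haplotypes):
            h1, h2 = line[chromosome]
            out[i] = _mosaic_at(h1, pos)[0] + _mosaic_at(h2, pos)[0]
        return out

    def breakpoints(self, line: int, chromosome: int) -> np.ndarray:
        """Genotype-relevant crossover positions (cM) of one line, i.e. the
        interior segment ends of either haplotype mosaic."""
        h1, h2 = self.haplotypes[line][chromosome]
        return np.unique(np.concatenate([h1[0][:-1], h2[0][:-1]]))


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Jittered, strictly increasing bp positions; cM by uniform scaling."""
    frames = []
    for c in range(config.n_chromosomes):
        n = config.n_snps_per_chrom
        lbp, lcm = config.chrom_lengths_bp[c], config.chrom_lengths_cM[c]
        spacing = lbp / n
        centers = (np.arange(n) + 0.5) * spacing
        j = config.marker_jitter
        jitter = rng.uniform(-j, j, size=n) * spacing if j > 0 else np.zeros(n)
        bp = np.clip(np.round(centers + jitter).astype(np.int64), 1, lbp)
        while np.any(np.diff(bp) <= 0):                     # break rounding ties
            dup = np.flatnonzero(np.diff(bp) <= 0) + 1
            bp[dup] += 1
            bp = np.maximum.accumulate(bp)
        frames.append(
            pd.DataFrame({"chrom": c, "pos_bp": bp, "cM": bp / lbp * lcm})
        )
    return pd.concat(frames, ignore_index=True)


def breed_ril_population(config: SimConfig, rng: np.random.Generator | None = None) -> TruePopulation:
    """Advance an F1 by single seed descent to ``config.n_generations``.

    Every line starts as the fully heterozygous F1 (one chromosome from
    each parent) and is selfed once per generation: two independent
    gametes of the current plant form the next.  With generation 1 the F1,
    generation ``t`` has expected per-locus heterozygosity ``0.5**(t-1)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    markers = _marker_positions(config, rng)

    haplotypes: list[list[tuple[Mosaic, Mosaic]]] = []
    for _ in range(config.n_lines):
        line = []
        for c in range(config.n_chromosomes):
            L = config.chrom_lengths_cM[c]
            h1: Mosaic = (np.array([L]), np.array([0], dtype=np.int8))
            h2: Mosaic = (np.array([L]), np.array([1], dtype=np.int8))
            pair = (h1, h2)
            for _gen in range(config.n_generations - 1):
                pair = (
                    simulate_meiosis(pair, L, rng),
                    simulate_meiosis(pair, L, rng),
                )
            line.append(pair)
        haplotypes.append(line)

    genotypes = np.empty((config.n_lines, len(markers)), dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    cm_arr = markers["cM"].to_numpy()
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_arr == c)
        pos = cm_arr[idx]
        for i, line in enumerate(haplotypes):
            h1, h2 = line[c]
            genotypes[i, idx] = _mosaic_at(h1, pos) + _mosaic_at(h2, pos)

    line_ids = [f"RIL{i + 1:03d}" for i in range(config.n_lines)]
    return TruePopulation(config, markers, genotypes, haplotypes, line_ids)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def observe_genotypes(
    pop: TruePopulation,
    mean_depth: float,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
    contaminated_line_fraction: float = 0.0,
    contamination_het_rate: float = 0.05,
) -> tuple[SNPCallSet, np.ndarray]:
    """Observe true genotypes through sequencing depth and error.

    Depth is Poisson(``mean_depth``) per call; each read draws one of the
    genotype's alleles and miscalls it with ``error_rate``.  The observed
    call is the maximum-likelihood genotype given the read pile-up, as a
    variant caller would emit: isolated miscalled reads do not flip a
    homozygote, while a true heterozygote whose sampled reads happen to
    cover only one allele collapses to that homozygote (the realistic
    source of "abnormal" calls at low depth).  Zero-depth and
    ``missing_rate``-masked calls are missing.  A fraction of lines is
    "contaminated": their true genotype is replaced by a heterozygote with
    ``contamination_het_rate`` per call before observation.  Each SNP is
    emitted on a random REF/ALT orientation with the matching parental
    calls.

    Returns the call set and the contaminated line indices.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    for rate in (error_rate, missing_rate, contaminated_line_fraction):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")

    G = pop.genotypes.copy()
    n_lines, n_snps = G.shape
    n_cont = int(round(contaminated_line_fraction * n_lines))
    cont = rng.choice(n_lines, size=n_cont, replace=False) if n_cont else np.array([], int)
    if n_cont:
        mask = rng.random((n_cont, n_snps)) < contamination_het_rate
        sub = G[cont]
        sub[mask] = AB
        G[cont] = sub

    depth = rng.poisson(mean_depth, size=G.shape)
    p_alt = G.astype(float) / 2.0
    p_eff = p_alt * (1 - error_rate) + (1 - p_alt) * error_rate
    alt_reads = rng.binomial(depth, p_eff)

    # maximum-likelihood genotype from (ref, alt) read counts
    e = min(max(error_rate, 1e-12), 0.5 - 1e-12)
    ref_reads = depth - alt_reads
    ll_aa = ref_reads * np.log(1 - e) + alt_reads * np.log(e)
    ll_ab = depth * np.log(0.5)
    ll_bb = ref_reads * np.log(e) + alt_reads * np.log(1 - e)
    obs = np.full(G.shape, AA, dtype=np.int8)
    obs[(ll_ab > ll_aa) & (ll_ab >= ll_bb)] = AB
    obs[(ll_bb > ll_aa) & (ll_bb > ll_ab)] = BB
    obs[depth == 0] = MISSING
    obs[rng.random(G.shape) < missing_rate] = MISSING

    # random REF/ALT orientation per SNP: parent 1 is sometimes the ALT hom
    flip = rng.random(n_snps) < 0.5
    col = obs[:, flip]
    swap = col.copy()
    swap[col == AA] = BB
    swap[col == BB] = AA
    obs[:, flip] = swap
    p1 = np.where(flip, BB, AA).astype(np.int8)
    p2 = np.where(flip, AA, BB).astype(np.int8)

    snps = pd.DataFrame(
        {
            "chrom": pop.markers["chrom"].to_numpy(),
            "pos": pop.markers["pos_bp"].to_numpy(),
            "p1": p1,
            "p2": p2,
        }
    )
    callset = SNPCallSet(
        snps=snps,
        calls=obs,
        depths=depth.astype(np.int32),
        line_ids=list(pop.line_ids),
    )
    return callset, np.sort(cont)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    pop: TruePopulation, qtl_specs: list[QTLSpec], rng: np.random.Generator
) -> pd.DataFrame:
    """Additive QTL phenotypes with noise calibrated to the target PVE.

    Each QTL contributes ``+a`` to aa lines, ``-a`` to bb lines and 0 to
    residual heterozygotes.  Per trait, the Gaussian noise variance is set
    from the realised genetic variance so that the summed QTL variance
    explains the summed target PVE.  Traits with no QTL are pure noise.
    ``NA`` (apex count) is rounded and clipped at zero.

    Returns a table with columns ``line_id``, ``NA``, ``R``, ``Q``.
    """
    out = pd.DataFrame({"line_id": pop.line_ids})
    for trait in TRAITS:
        specs = [q for q in qtl_specs if q.trait == trait]
        baseline = TRAIT_BASELINES[trait]
        if not specs:
            y = baseline + rng.normal(0.0, NULL_NOISE_SD[trait], size=pop.n_lines)
        else:
            g = np.zeros(pop.n_lines)
            for q in specs:
                code = 1.0 - pop.genotypes_at(q.chromosome, q.position_cM).astype(float)
                g += q.additive_effect * code          # aa:+a, ab:0, bb:-a
            var_g = float(np.var(g))
            if var_g == 0:
                raise ValueError(f"QTL for {trait} are monomorphic in this population")
            pve_tot = sum(q.target_pve for q in specs)
            if pve_tot >= 100:
                raise ValueError("summed target PVE must be below 100")
            sigma2 = var_g * (100.0 - pve_tot) / pve_tot
            y = baseline + g + rng.normal(0.0, np.sqrt(sigma2), size=pop.n_lines)
        if trait == "NA":
            y = np.maximum(np.round(y), 0.0)
        out[trait] = y
    return out


# ---------------------------------------------------------------------------
# parametric leaf outlines
# ---------------------------------------------------------------------------

@dataclass
class LeafShapeSpec:
    """Parameters of one synthetic leaflet outline.

    ``lobe_depth`` in [0, 1) pulls a notch vertex from the margin chord
    toward the main vein on both sides (0 = no lobing); ``n_apexes`` >= 2
    counts margin apexes (2 = smooth ovate, more = indented margin);
    ``notch_position`` in (0, 1) places the deepest concave-point pair
    along the main vein as a fraction of its length, so the length ratio
    Q equals ``100 * notch_position`` by construction.
    """

    lobe_depth: float = 0.0
    n_apexes: int = 2
    notch_position: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.lobe_depth < 1:
            raise ValueError("lobe_depth must lie in [0, 1)")
        if self.n_apexes < 2:
            raise ValueError("a leaf outline has at least 2 apexes (tip and base)")
        if not 0 < self.notch_position <= 1:
            raise ValueError("notch_position must lie in (0, 1]")


@dataclass
class LeafShape:
    """A leaf outline polygon with landmark annotations and analytic truth."""

    vertices: np.ndarray                    # (n, 2), counterclockwise
    tip_index: int
    base_index: int
    concave_pairs: list[tuple[int, int]]    # (right, left) notch-vertex indices
    apex_indices: list[int]
    analytic: dict[str, float]              # V, lobed_area, L1, L2
    spec: LeafShapeSpec | None = None


def generate_leaf_polygon(
    spec: LeafShapeSpec, n_vertices: int = 256, bump_amplitude: float = 0.08
) -> LeafShape:
    """Build a leaflet polygon realising a :class:`LeafShapeSpec`.

    The blade is an ellipse with the main vein as its long axis (base at
    the origin, tip above it).  Indented margins superimpose ``n_apexes``
    radial bumps; lobed leaves cut a wedge notch on both sides at the
    notch position, whose vertex sits ``lobe_depth`` of the way from the
    margin chord to the vein.  Analytic blade area ``V``, lobed (notch)
    area, ``L1`` and ``L2`` are recorded; the polygon reproduces them to
    well under 1%.
    """
    if n_vertices % 2 or n_vertices < 64:
        raise ValueError("n_vertices must be even and >= 64")
    bumped = spec.n_apexes > 2
    # long/short semi-axes; the indented family is rounder so each bump is
    # a strict local maximum of centroid distance
    a, b = (0.45, 0.40) if bumped else (0.5, 0.3)
    amp = bump_amplitude if bumped else 0.0
    center = np.array([0.0, a])
    L2 = 2 * a

    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    base_pts = np.column_stack([b * np.sin(t), a - a * np.cos(t)])
    radial = base_pts - center
    pts = center + radial * (1 + amp * np.cos(spec.n_apexes * t))[:, None]

    records: list[tuple[float, np.ndarray, str]] = [
        (float(tt), p, "") for tt, p in zip(t, pts)
    ]

    analytic_lobed = 0.0
    wedge_area_removed = 0.0
    if spec.lobe_depth > 0:
        delta = min(0.18, 0.8 * min(spec.notch_position, 1 - spec.notch_position) * L2)
        if delta <= 0:
            raise ValueError("notch_position leaves no room for a notch")
        y0 = spec.notch_position * L2
        ylo, yhi = y0 - delta, y0 + delta

        def margin_x(y: float) -> float:
            return b * float(np.sqrt(max(0.0, 1 - ((y - a) / a) ** 2)))

        x_lo, x_hi = margin_x(ylo), margin_x(yhi)
        x_cm = 0.5 * (x_lo + x_hi)                   # chord midpoint abscissa
        x_deep = (1 - spec.lobe_depth) * x_cm
        t_of = lambda y: float(np.arccos(1 - y / a))
        t_lo, t_mid, t_hi = t_of(ylo), t_of(y0), t_of(yhi)
        # drop base samples inside the notch t-range on both sides
        records = [
            r
            for r in records
            if not (t_lo < r[0] < t_hi or 2 * np.pi - t_hi < r[0] < 2 * np.pi - t_lo)
        ]
        records += [
            (t_lo, np.array([x_lo, ylo]), "shoulder"),
            (t_mid, np.array([x_deep, y0]), "deep_right"),
            (t_hi, np.array([x_hi, yhi]), "shoulder"),
            (2 * np.pi - t_hi, np.array([-x_hi, yhi]), "shoulder"),
            (2 * np.pi - t_mid, np.array([-x_deep, y0]), "deep_left"),
            (2 * np.pi - t_lo, np.array([-x_lo, ylo]), "shoulder"),
        ]
        records.sort(key=lambda r: r[0])
        # chord-closure convention: lobed area per side is the region between
        # the shoulder chord and the notch polyline, a closed-form trapezoid
        analytic_lobed = 2 * delta * x_cm * spec.lobe_depth
        # area removed from the smooth blade by each notch (slice minus polyline)
        u1, u2 = (ylo - a) / a, (yhi - a) / a
        slice_area = a * b * 0.5 * (
            (u2 * np.sqrt(1 - u2**2) + np.arcsin(u2))
            - (u1 * np.sqrt(1 - u1**2) + np.arcsin(u1))
        )
        wedge_area_removed = 2 * (slice_area - delta * (x_cm + x_deep))

    verts = np.array([r[1] for r in records])
    tags = [r[2] for r in records]
    ts = np.array([r[0] for r in records])

    base_index = int(np.argmin(np.abs(ts)))
    tip_index = int(np.argmin(np.abs(ts - np.pi)))
    concave_pairs = []
    if spec.lobe_depth > 0:
        concave_pairs = [(tags.index("deep_right"), tags.index("deep_left"))]
    if bumped:
        apex_ts = 2 * np.pi * np.arange(spec.n_apexes) / spec.n_apexes
        apex_indices = sorted(
            int(np.argmin(np.minimum(np.abs(ts - at), 2 * np.pi - np.abs(ts - at))))
            for at in apex_ts
        )
    else:
        apex_indices = sorted({base_index, tip_index})

    # analytic blade area: finely sampled smooth outline minus the notches
    tf = np.linspace(0.0, 2 * np.pi, 8 * n_vertices, endpoint=False)
    bf = np.column_stack([b * np.sin(tf), a - a * np.cos(tf)])
    pf = center + (bf - center) * (1 + amp * np.cos(spec.n_apexes * tf))[:, None]
    V_smooth = _shoelace(pf)
    analytic = {
        "V": float(V_smooth - wedge_area_removed),
        "lobed_area": float(analytic_lobed),
        "L1": float(spec.notch_position * L2) if spec.lobe_depth > 0 else float(L2),
        "L2": float(L2),
    }
    return LeafShape(verts, tip_index, base_index, concave_pairs, apex_indices, analytic, spec)


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def truth_bins_and_map(pop: TruePopulation):
    """Ground-truth bin markers and genetic map straight from the simulation.

    Every simulated SNP becomes a single-SNP bin carrying the true
    genotypes, and linkage groups take the true cM positions.  This
    isolates downstream stages (ordering, scanning) from genotyping noise
    when that is what a test or analysis wants.
    """
    from .genotype import BinMarker, BinSet
    from .linkage import GeneticMap, LinkageGroup

    chrom_arr = pop.markers["chrom"].to_numpy()
    bp = pop.markers["pos_bp"].to_numpy()
    cm = pop.markers["cM"].to_numpy()
    bins, groups = [], []
    for c in range(pop.config.n_chromosomes):
        idx = np.flatnonzero(chrom_arr == c)
        ids = [f"bin{c:02d}_{k:04d}" for k in range(idx.size)]
        for k, i in enumerate(idx):
            bins.append(
                BinMarker(ids[k], c, int(bp[i]), int(bp[i]), pop.genotypes[:, i].copy(), 1)
            )
        groups.append(
            LinkageGroup(
                id=f"LG{c + 1}",
                chromosome=c,
                bin_ids=ids,
                positions_cM=cm[idx] - cm[idx][0],
                start_bp=bp[idx],
                end_bp=bp[idx],
            )
        )
    return BinSet(bins, list(pop.line_ids)), GeneticMap(groups)


def leaf_spec_for_phenotype(R: float, Q: float, NA: float) -> LeafShapeSpec:
    """Invert the shape family: a spec whose measured R, Q, NA match the
    given phenotype values (R and Q in percent).  Values are clipped to
    the family's feasible range."""
    n_apexes = max(2, int(round(NA)))
    notch = min(max(Q / 100.0, 0.2), 0.8)
    if R >= 100:
        return LeafShapeSpec(0.0, n_apexes, notch)
    # solve lobed = V * (100/R - 1) for lobe_depth via the chord-area formula
    probe = generate_leaf_polygon(LeafShapeSpec(0.5, 2, notch))
    unit = probe.analytic["lobed_area"] / 0.5        # lobed area per unit depth
    target = probe.analytic["V"] * (100.0 / R - 1.0)
    depth = min(max(target / unit, 0.02), 0.95)
    return LeafShapeSpec(depth, n_apexes, notch)
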