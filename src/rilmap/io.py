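"""File formats, configuration and the pipeline driver.

Conventions, stated once and enforced by round-trip tests:

* VCF positions are 1-based (per the standard); all internal bp spans are
  1-based inclusive; BED exports are 0-based half-open.
* Genotypes on disk use one character: ``A`` (parent-1 homozygote), ``B``
  (parent-2 homozygote), ``H`` (heterozygote), ``-`` (missing).
* Every output file begins with ``#`` comment headers carrying the package
  version, the seed and the relevant parameters, so a run is identifiable
  and byte-reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype import (
    AA, AB, BB, MISSING, GENOTYPE_CHARS,
    BinMarker, BinSet, GenotyperParams, SNPCallSet, genotype_pipeline,
)
from .linkage import GeneticMap, LinkageGroup, build_map, map_summary
from .qtl import QTLResult, ScanParams, scan_trait
from .simulate import (
    LeafShape, SimConfig, QTLSpec, breed_ril_population, observe_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

_CODE_TO_CHAR = {AA: "A", AB: "H", BB: "B", MISSING: "-"}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}


def _header(seed: int | None = None, **params) -> str:
    parts = [f"# rilmap {__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    for k, v in params.items():
        parts.append(f"# {k}={v}")
    return "\n".join(parts) + "\n"


def _write_frame(df: pd.DataFrame, path: Path, seed: int | None = None, **params) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, **params))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP call sets: VCF and TSV
# ---------------------------------------------------------------------------

def write_vcf(callset: SNPCallSet, path: str | Path, seed: int | None = None) -> None:
    """Minimal VCF (GT and DP) with the two parent columns first."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=rilmap{__version__}\n")
        if seed is not None:
            fh.write(f"##rilmap_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        samples = ["P1", "P2"] + list(callset.line_ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        snps = callset.snps
        for j in range(callset.n_snps):
            chrom = f"chr{int(snps['chrom'].iloc[j]) + 1}"
            fields = [chrom, str(int(snps["pos"].iloc[j])), ".", "A", "T", ".", "PASS", ".", "GT:DP"]
            fields.append(f"{gt[int(snps['p1'].iloc[j])]}:99")
            fields.append(f"{gt[int(snps['p2'].iloc[j])]}:99")
            for i in range(callset.n_lines):
                d = int(callset.depths[i, j]) if callset.depths is not None else 0
                fields.append(f"{gt[int(callset.calls[i, j])]}:{d}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, parent_names: tuple[str, str] = ("P1", "P2")) -> SNPCallSet:
    """Read a VCF with GT and DP into a call set.

    Multi-allelic and indel records are skipped (counted in the log).
    Raises when a parent sample or the DP format field is absent.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input; use the TSV dialect instead") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in parent_names:
        if p not in samples:
            raise ValueError(f"parent sample {p!r} not found in VCF (samples: {samples[:5]}...)")
    ip1, ip2 = samples.index(parent_names[0]), samples.index(parent_names[1])
    line_idx = [k for k in range(len(samples)) if k not in (ip1, ip2)]
    line_ids = [samples[k] for k in line_idx]

    rows, call_rows, depth_rows = [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            raise ValueError("VCF lacks the DP format field; supply the TSV dialect instead")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = v.gt_types
        code = np.full(len(samples), MISSING, dtype=np.int8)
        code[g == 0] = AA
        code[g == 1] = AB
        code[g == 3] = BB
        chrom = int(str(v.CHROM).removeprefix("chr")) - 1
        rows.append((chrom, v.POS, code[ip1], code[ip2]))
        call_rows.append(code[line_idx])
        depth_rows.append(np.maximum(dp.reshape(-1)[line_idx], 0))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/indel records", n_skipped)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "p1", "p2"])
    return SNPCallSet(
        snps=snps,
        calls=np.array(call_rows, dtype=np.int8).T,
        depths=np.array(depth_rows, dtype=np.int32).T,
        line_ids=line_ids,
    )


def write_calls_tsv(callset: SNPCallSet, path: str | Path, seed: int | None = None) -> None:
    """TSV dialect: chrom, pos, p1, p2 then one A/H/B/- column per line;
    a sibling ``<path>.depths`` file carries the depth matrix."""
    chars = GENOTYPE_CHARS[callset.calls]
    df = pd.DataFrame(
        {
            "chrom": callset.snps["chrom"],
            "pos": callset.snps["pos"],
            "p1": GENOTYPE_CHARS[callset.snps["p1"].to_numpy()],
            "p2": GENOTYPE_CHARS[callset.snps["p2"].to_numpy()],
        }
    )
    for i, lid in enumerate(callset.line_ids):
        df[lid] = chars[i]
    _write_frame(df, Path(path), seed)
    if callset.depths is not None:
        ddf = pd.DataFrame(callset.depths.T, columns=callset.line_ids)
        _write_frame(ddf, Path(str(path) + ".depths"), seed)


def read_calls_tsv(path: str | Path) -> SNPCallSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    line_ids = [c for c in df.columns if c not in ("chrom", "pos", "p1", "p2")]
    to_code = np.vectorize(_CHAR_TO_CODE.get, otypes=[np.int8])
    depths = None
    dpath = Path(str(path) + ".depths")
    if dpath.exists():
        depths = pd.read_csv(dpath, sep="\t", comment="#").to_numpy().T.astype(np.int32)
    return SNPCallSet(
        snps=pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"],
                "p1": to_code(df["p1"].to_numpy()),
                "p2": to_code(df["p2"].to_numpy()),
            }
        ),
        calls=to_code(df[line_ids].to_numpy()).T,
        depths=depths,
        line_ids=line_ids,
    )


def read_snp_calls(
    path: str | Path, parent_names: tuple[str, str] = ("P1", "P2")
) -> SNPCallSet:
    """Dispatch on extension: ``.vcf`` via cyvcf2, anything else as TSV."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path, parent_names)
    return read_calls_tsv(path)


# ---------------------------------------------------------------------------
# bins, maps, phenotypes, QTL tables
# ---------------------------------------------------------------------------

def write_bins_tsv(binset: BinSet, path: str | Path, seed: int | None = None) -> None:
    df = binset.frame()
    chars = GENOTYPE_CHARS[binset.matrix()]
    for i, lid in enumerate(binset.line_ids):
        df[lid] = chars[i]
    _write_frame(df, Path(path), seed)


def read_bins_tsv(path: str | Path) -> BinSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["id", "chrom", "start_bp", "end_bp", "n_snps"]
    line_ids = [c for c in df.columns if c not in meta]
    to_code = np.vectorize(_CHAR_TO_CODE.get, otypes=[np.int8])
    bins = []
    for k, row in df.iterrows():
        try:
            bins.append(
                BinMarker(
                    id=str(row["id"]),
                    chromosome=int(row["chrom"]),
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    genotypes=to_code(row[line_ids].to_numpy()),
                    n_snps=int(row["n_snps"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"corrupt bins file {path} at data line {k + 1}: {exc}") from exc
    return BinSet(bins, line_ids)


def write_map_tsv(gmap: GeneticMap, path: str | Path, seed: int | None = None) -> None:
    _write_frame(gmap.frame(), Path(path), seed)


def read_map_tsv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    groups = []
    for lg, sub in df.groupby("lg", sort=False):
        groups.append(
            LinkageGroup(
                id=str(lg),
                chromosome=int(sub["chrom"].iloc[0]),
                bin_ids=list(sub["marker"]),
                positions_cM=sub["cM"].to_numpy(float),
                start_bp=sub["start_bp"].to_numpy(int),
                end_bp=sub["end_bp"].to_numpy(int),
            )
        )
    return GeneticMap(groups)


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    _write_frame(pheno.round(4), Path(path), seed)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_qtl_tsv(
    results: list[QTLResult], path: str | Path, seed: int | None = None, **params
) -> None:
    cols = [
        "trait", "method", "name", "lg", "left_marker", "right_marker",
        "phys_start_bp", "phys_end_bp", "peak_cM", "lod", "pve", "additive",
        "threshold", "ci_lo_cM", "ci_hi_cM",
    ]
    rows = [
        {
            "trait": q.trait, "method": "ICIM-ADD", "name": q.name, "lg": q.lg,
            "left_marker": q.left_marker, "right_marker": q.right_marker,
            "phys_start_bp": q.phys_start_bp, "phys_end_bp": q.phys_end_bp,
            "peak_cM": round(q.peak_cM, 4), "lod": round(q.lod, 2),
            "pve": round(q.pve, 2), "additive": round(q.additive, 4),
            "threshold": round(q.threshold, 2),
            "ci_lo_cM": round(q.ci_lo_cM, 4), "ci_hi_cM": round(q.ci_hi_cM, 4),
        }
        for q in results
    ]
    _write_frame(pd.DataFrame(rows, columns=cols), Path(path), seed, **params)


def write_breakpoints_bed(pop, path: str | Path, seed: int | None = None) -> None:
    """True haplotype segments as BED-like TSV (0-based half-open bp)."""
    rows = []
    for i, line in enumerate(pop.haplotypes):
        for c, pair in enumerate(line):
            lcm = pop.config.chrom_lengths_cM[c]
            lbp = pop.config.chrom_lengths_bp[c]
            for h, (ends, origins) in enumerate(pair):
                start = 0.0
                for e, o in zip(ends, origins):
                    rows.append(
                        (
                            f"chr{c + 1}",
                            int(round(start / lcm * lbp)),
                            int(round(e / lcm * lbp)),
                            f"{pop.line_ids[i]}:hap{h + 1}:P{o + 1}",
                        )
                    )
                    start = e
    _write_frame(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]), Path(path), seed)


def write_leaf_shapes_json(shapes: dict[str, LeafShape], path: str | Path) -> None:
    records = []
    for lid, s in shapes.items():
        records.append(
            {
                "line_id": lid,
                "vertices": np.asarray(s.vertices).round(8).tolist(),
                "tip_index": s.tip_index,
                "base_index": s.base_index,
                "concave_pairs": [list(p) for p in s.concave_pairs],
                "apex_indices": list(map(int, s.apex_indices)),
                "analytic": s.analytic,
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(records))


def read_leaf_shapes_json(path: str | Path) -> dict[str, LeafShape]:
    out = {}
    for rec in json.loads(Path(path).read_text()):
        out[rec["line_id"]] = LeafShape(
            vertices=np.asarray(rec["vertices"], dtype=float),
            tip_index=int(rec["tip_index"]),
            base_index=int(rec["base_index"]),
            concave_pairs=[tuple(p) for p in rec["concave_pairs"]],
            apex_indices=list(rec["apex_indices"]),
            analytic=rec.get("analytic", {}),
        )
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    genotyper: GenotyperParams = field(default_factory=GenotyperParams)
    scan: ScanParams = field(default_factory=ScanParams)
    out_dir: str = "rilmap_out"
    seed: int = 0
    parent_names: tuple[str, str] = ("P1", "P2")
    input_calls: str | None = None      # skip simulation when set
    traits: tuple[str, ...] = ("NA", "R", "Q")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim_raw = raw.pop("sim", {})
        qtls = [QTLSpec(**q) for q in sim_raw.pop("qtl_specs", [])]
        sim = SimConfig(**sim_raw, qtl_specs=qtls)
        gen = GenotyperParams(**raw.pop("genotyper", {}))
        scan = ScanParams(**raw.pop("scan", {}))
        return cls(sim=sim, genotyper=gen, scan=scan, **raw)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """simulate (optional) -> genotype -> map -> qtl -> report.

    Returns the in-memory stage products; files land under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng = np.random.default_rng(seed)

    if config.input_calls is None:
        cfg = dataclasses.replace(config.sim, seed=seed)
        pop = breed_ril_population(cfg)
        callset, _ = observe_genotypes(
            pop, cfg.mean_depth, cfg.error_rate, cfg.missing_rate, rng,
            cfg.contaminated_line_fraction, cfg.contamination_het_rate,
        )
        pheno = simulate_phenotypes(pop, cfg.qtl_specs, rng)
        write_vcf(callset, out / "calls.vcf", seed)
        write_breakpoints_bed(pop, out / "true_breakpoints.bed.tsv", seed)
        write_phenotypes_tsv(pheno, out / "phenotypes.tsv", seed)
    else:
        callset = read_snp_calls(config.input_calls, config.parent_names)
        pheno = read_phenotypes_tsv(out / "phenotypes.tsv")

    binset, reports = genotype_pipeline(callset, config.genotyper)
    write_bins_tsv(binset, out / "bins.tsv", seed)
    for name, rep in reports.items():
        if len(rep.removals):
            _write_frame(rep.removals, out / f"removed_{name}.tsv", seed, stage=name)

    gmap, link_report = build_map(binset, rng)
    write_map_tsv(gmap, out / "map.tsv", seed)
    _write_frame(map_summary(gmap), out / "map_summary.tsv", seed)
    if len(link_report):
        _write_frame(link_report, out / "unlinked_bins.tsv", seed)

    pheno_lines = pheno.set_index("line_id").loc[
        [l for l in binset.line_ids if l in set(pheno["line_id"])]
    ]
    results: list[QTLResult] = []
    profiles = {}
    for trait in config.traits:
        y = pheno_lines[trait].to_numpy(float)
        profile, threshold, calls = scan_trait(
            gmap, binset, y, config.scan, trait, np.random.default_rng(seed + 1)
        )
        profiles[trait] = profile
        results.extend(calls)
        _write_frame(profile.round(4), out / f"lod_profile_{trait}.tsv", seed, trait=trait)
    write_qtl_tsv(results, out / "qtl.tsv", seed, alpha=config.scan.alpha,
                  permutations=config.scan.n_permutations)
    return {
        "callset": callset, "binset": binset, "map": gmap,
        "phenotypes": pheno, "qtl": results, "profiles": profiles,
        "reports": reports,
    }
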