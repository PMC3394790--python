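"""End-to-end pipeline: stage functions over files, run orchestration,
manifest emission and the planted-truth recovery report.

Each stage reads the standard input files, runs the corresponding library
module, and writes deterministic TSV/JSON outputs. :func:`run_pipeline`
wires the stages in dependency order (simulate -> audit/stats/concord/
blocks/roh -> gwas-xref -> report), halting on the first failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .concordance import (
    ConcordanceConfig,
    match_with_slippage,
    restrict_to_shared_samples,
    venn_counts,
)
from .genomic_io import (
    ValidationError,
    read_bed,
    read_gene_models,
    read_gwas_catalog,
    read_probe_manifest,
    read_report_tsv,
    read_vcf,
    write_report_tsv,
)
from .ld_blocks import (
    LdConfig,
    RohConfig,
    block_summary,
    find_roh,
    gabriel_blocks,
    ld_subsample_experiment,
    matrix_from_sites,
    roh_total,
    trim_by_call_rate,
)
from .probe_audit import (
    ALL_FLAGS,
    AuditConfig,
    audit_probes,
    audit_summary,
    flag_gwas_studies,
    offset_histogram,
    saturation_curve,
)
from .synthetic import StudySpec, ViewParams, generate_study
from .variant_stats import (
    cohort_summary,
    count_het_dual_nonref,
    find_polyallelic_sites,
    multi_snp_burden,
)

__all__ = [
    "ConfigError",
    "StageError",
    "stage_audit",
    "stage_gwas_xref",
    "stage_stats",
    "stage_burden",
    "stage_concord",
    "stage_blocks",
    "stage_blocks_subsample",
    "stage_roh",
    "run_pipeline",
    "render_report",
]


log = logging.getLogger("refaudit.pipeline")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage functions (file-level)
# ---------------------------------------------------------------------------


def stage_audit(
    vcf: Path,
    probes_tsv: Path,
    sv_bed: Optional[Path],
    out_prefix: Path,
    config: AuditConfig = AuditConfig(),
    saturation_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    saturation_replicates: int = 20,
    seed: int = 0,
) -> dict:
    """Probe audit: per-probe flags, platform summary, offset histogram and
    saturation curve, written as four TSVs under ``out_prefix``."""
    _, sites = read_vcf(vcf)
    probes = read_probe_manifest(probes_tsv)
    svs = read_bed(sv_bed) if sv_bed else []
    flags = audit_probes(probes, sites, svs, config)

    flag_rows = [
        {
            "probe_id": pid,
            "flags": ",".join(sorted(pf.flags)) or ".",
            "offsets": ",".join(str(o) for o in sorted(pf.offsets)) or ".",
        }
        for pid, pf in sorted(flags.items())
    ]
    write_report_tsv(flag_rows, f"{out_prefix}.flags.tsv",
                     columns=["probe_id", "flags", "offsets"])

    platforms = sorted({p.platform for p in probes})
    summary_rows = []
    for platform in platforms:
        sub = {p.probe_id: flags[p.probe_id] for p in probes if p.platform == platform}
        summary_rows.append(audit_summary(sub, platform).as_row())
    write_report_tsv(summary_rows, f"{out_prefix}.summary.tsv")

    hist = offset_histogram(probes, sites, config)
    write_report_tsv(
        [{"offset": k, "count": v} for k, v in sorted(hist.items())],
        f"{out_prefix}.offsets.tsv",
    )
    sat = saturation_curve(
        probes, sites, saturation_fractions, saturation_replicates, seed, config
    )
    write_report_tsv(sat, f"{out_prefix}.saturation.tsv")
    return {
        "n_probes": len(probes),
        "summaries": summary_rows,
        "flagged_probe_ids": sorted(pid for pid, pf in flags.items() if pf.flags),
    }


def stage_gwas_xref(catalog_tsv: Path, flags_tsv: Path, probes_tsv: Path,
                    out_path: Path) -> dict:
    """Cross-reference the association catalog against flagged probes."""
    catalog = read_gwas_catalog(catalog_tsv)
    probes = read_probe_manifest(probes_tsv)
    flagged = {
        row["probe_id"]
        for row in read_report_tsv(flags_tsv)
        if row["flags"] != "."
    }
    affected, fraction = flag_gwas_studies(catalog, flagged, probes)
    write_report_tsv(
        [
            {"study_id": sid, "affected": int(hit)}
            for sid, hit in sorted(affected.items())
        ],
        out_path,
    )
    return {
        "n_studies": len(affected),
        "n_affected": sum(affected.values()),
        "affected_fraction": fraction,
    }


def stage_stats(vcf: Path, out_prefix: Path) -> dict:
    """Polyallelic site list and per-sample dual-non-reference counts."""
    samples, sites = read_vcf(vcf)
    poly = find_polyallelic_sites(sites)
    write_report_tsv(
        [{"chrom": c.chrom, "pos": c.pos} for c in poly],
        f"{out_prefix}.polyallelic.tsv",
        columns=["chrom", "pos"],
    )
    counts = [count_het_dual_nonref(sites, i) for i in range(len(samples))]
    write_report_tsv(
        [
            {"sample": s, "het_dual_nonref": c}
            for s, c in zip(samples, counts)
        ],
        f"{out_prefix}.dual_nonref.tsv",
    )
    mean, sd = cohort_summary(counts) if counts else (0.0, None)
    return {
        "n_polyallelic": len(poly),
        "dual_nonref_mean": mean,
        "dual_nonref_sd": sd,
    }


def stage_burden(vcf: Path, genes_tsv: Path, out_path: Path,
                 region_kind: str = "exon") -> dict:
    """Per-sample multi-variant burden over gene models."""
    samples, sites = read_vcf(vcf)
    genes = read_gene_models(genes_tsv)
    rows = []
    for i, name in enumerate(samples):
        b = multi_snp_burden(sites, genes, i, region_kind=region_kind)
        rows.append(
            {
                "sample": name,
                "n_genes_multi": b.n_genes_multi,
                "n_exons_multi": b.n_exons_multi,
            }
        )
    write_report_tsv(rows, out_path)
    gm, gs = cohort_summary([r["n_genes_multi"] for r in rows])
    em, es = cohort_summary([r["n_exons_multi"] for r in rows])
    return {
        "genes_multi_mean": gm, "genes_multi_sd": gs,
        "exons_multi_mean": em, "exons_multi_sd": es,
    }


def stage_concord(
    vcf_a: Path,
    vcf_b: Path,
    out_prefix: Path,
    config: ConcordanceConfig = ConcordanceConfig(),
    shared_samples_only: bool = False,
) -> dict:
    """Slippage-tolerant partition of two call sets (shared / unique)."""
    samples_a, sites_a = read_vcf(vcf_a)
    samples_b, sites_b = read_vcf(vcf_b)
    if shared_samples_only:
        sites_a, sites_b = restrict_to_shared_samples(
            samples_a, sites_a, samples_b, sites_b
        )
    result = match_with_slippage(sites_a, sites_b, config)
    rows = (
        [
            {"set": "shared", "chrom": pa[0], "pos_a": pa[1], "pos_b": pb[1]}
            for pa, pb in result.pairs
        ]
        + [
            {"set": "unique_a", "chrom": c, "pos_a": p, "pos_b": ""}
            for c, p in result.unique_a
        ]
        + [
            {"set": "unique_b", "chrom": c, "pos_a": "", "pos_b": p}
            for c, p in result.unique_b
        ]
    )
    write_report_tsv(rows, f"{out_prefix}.partition.tsv",
                     columns=["set", "chrom", "pos_a", "pos_b"])
    counts = venn_counts(result)
    with open(f"{out_prefix}.venn.json", "wt") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
    return counts


def stage_blocks(
    vcf: Path,
    out_path: Path,
    ld_config: LdConfig = LdConfig(),
    min_call_rate: float = 0.99,
) -> dict:
    """Call-rate trim, Gabriel-style block partition and block summary."""
    samples, sites = read_vcf(vcf)
    matrix = trim_by_call_rate(matrix_from_sites(samples, sites), min_call_rate)
    blocks = gabriel_blocks(matrix, ld_config)
    positions = matrix.positions()
    write_report_tsv(
        [
            {
                "chrom": b.chrom,
                "first_marker": b.first_marker,
                "last_marker": b.last_marker,
                "start_pos": int(positions[b.first_marker]),
                "end_pos": int(positions[b.last_marker]),
                "span_bp": b.span_bp,
            }
            for b in blocks
        ],
        out_path,
        columns=["chrom", "first_marker", "last_marker", "start_pos", "end_pos",
                 "span_bp"],
    )
    summary = block_summary(blocks)
    summary["n_markers"] = matrix.n_markers
    return summary


def stage_blocks_subsample(
    vcf: Path,
    out_path: Path,
    marker_fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    sample_fractions: tuple[float, ...] = (1.0,),
    replicates: int = 3,
    seed: int = 0,
    ld_config: LdConfig = LdConfig(),
    min_call_rate: float = 0.99,
) -> dict:
    """Mean block span across a marker/sample subsampling grid."""
    samples, sites = read_vcf(vcf)
    matrix = trim_by_call_rate(matrix_from_sites(samples, sites), min_call_rate)
    grid = ld_subsample_experiment(
        matrix, marker_fractions, sample_fractions, replicates, seed, ld_config
    )
    write_report_tsv(grid, out_path)
    return {"grid": grid}


def stage_roh(
    vcf: Path,
    out_path: Path,
    samples_wanted: Optional[list[str]] = None,
    config: RohConfig = RohConfig(),
) -> dict:
    """Runs of homozygosity per sample, with per-genome totals."""
    samples, sites = read_vcf(vcf)
    matrix = matrix_from_sites(samples, sites)
    wanted = samples_wanted or samples
    rows = []
    totals = []
    for name in wanted:
        segs = find_roh(matrix, name, config)
        totals.append(roh_total(segs))
        for s in segs:
            rows.append(
                {
                    "sample": s.sample,
                    "chrom": s.chrom,
                    "start_pos": s.start_pos,
                    "end_pos": s.end_pos,
                    "n_markers": s.n_markers,
                    "span_bp": s.span_bp,
                }
            )
    write_report_tsv(rows, out_path,
                     columns=["sample", "chrom", "start_pos", "end_pos",
                              "n_markers", "span_bp"])
    mean, sd = cohort_summary(totals) if totals else (0.0, None)
    return {"n_segments": len(rows), "total_bp_mean": mean, "total_bp_sd": sd}


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "study", "audit", "concordance", "ld", "roh",
    "min_call_rate", "log_level",
}
_ALL_STAGES = ("simulate", "audit", "stats", "burden", "concord", "blocks",
               "roh", "gwas-xref", "report")


def _build(cls, mapping: dict, name: str):
    try:
        return cls(**(mapping or {}))
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"bad {name} config: {exc}") from exc


def run_pipeline(config: dict, out_dir: Optional[Path] = None) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    ``config`` is the parsed YAML mapping. Unknown keys, missing inputs and
    invalid stage configs raise :class:`ConfigError` before any stage runs;
    a failure inside a stage raises :class:`StageError` naming the stage.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("config must set an explicit seed")
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out_dir", "refaudit_run"))
    stages = tuple(config.get("stages", _ALL_STAGES))
    bad = set(stages) - set(_ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")

    study_cfg = dict(config.get("study") or {})
    if "view_params" in study_cfg:
        study_cfg["view_params"] = _build(ViewParams, study_cfg["view_params"],
                                          "view_params")
    study = _build(StudySpec, study_cfg, "study")
    audit_cfg = _build(AuditConfig, config.get("audit"), "audit")
    concord_cfg = _build(ConcordanceConfig, config.get("concordance"), "concordance")
    ld_keys = dict(config.get("ld") or {})
    subsample_keys = {
        k: ld_keys.pop(k)
        for k in ("marker_fractions", "sample_fractions", "replicates")
        if k in ld_keys
    }
    ld_cfg = _build(LdConfig, ld_keys, "ld")
    roh_cfg = _build(RohConfig, config.get("roh"), "roh")
    min_call_rate = float(config.get("min_call_rate", 0.99))

    data = out / "data"
    results = out / "results"
    if "simulate" not in stages:
        required = ["cohort.vcf", "probes.tsv", "svs.bed", "genes.tsv",
                    "gwas.tsv", "view_a.vcf", "view_b.vcf"]
        missing = [f for f in required if not (data / f).exists()]
        needed_by = set(stages) & {"audit", "stats", "burden", "concord",
                                   "blocks", "roh", "gwas-xref"}
        if missing and needed_by:
            raise ConfigError(
                f"stages {sorted(needed_by)} need inputs under {data}, "
                f"missing: {missing}"
            )

    manifest: dict = {
        "tool_version": __version__,
        "config": {
            "seed": seed,
            "stages": list(stages),
            "study": {
                k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                for k, v in asdict(study).items()
            },
            "audit": asdict(audit_cfg),
            "concordance": asdict(concord_cfg),
            "ld": asdict(ld_cfg),
            "ld_subsample": subsample_keys,
            "roh": asdict(roh_cfg),
            "min_call_rate": min_call_rate,
        },
        "inputs": {},
        "stages": {},
    }
    results.mkdir(parents=True, exist_ok=True)
    summaries: dict = {}

    def _run_stage(name, fn, *args, **kwargs):
        log.info("stage %s: starting", name)
        t0 = time.monotonic()
        try:
            summaries[name] = fn(*args, **kwargs)
        except (ConfigError,):
            raise
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        elapsed = round(time.monotonic() - t0, 3)
        headline = {
            k: v for k, v in summaries[name].items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        log.info("stage %s: done in %.1fs %s", name, elapsed, headline)
        manifest["stages"][name] = {
            "wall_clock_s": elapsed,
            "summary": summaries[name],
        }

    if "simulate" in stages:
        _run_stage("simulate", generate_study, data, seed, study)
    for f in sorted(data.glob("*")) if data.exists() else []:
        manifest["inputs"][f.name] = _digest(f)

    if "audit" in stages:
        _run_stage(
            "audit", stage_audit,
            data / "cohort.vcf", data / "probes.tsv", data / "svs.bed",
            results / "audit", audit_cfg, seed=seed,
        )
    if "stats" in stages:
        _run_stage("stats", stage_stats, data / "cohort.vcf", results / "stats")
    if "burden" in stages:
        _run_stage("burden", stage_burden, data / "cohort.vcf",
                   data / "genes.tsv", results / "burden.tsv")
    if "concord" in stages:
        _run_stage("concord", stage_concord, data / "view_a.vcf",
                   data / "view_b.vcf", results / "concord", concord_cfg)
    if "blocks" in stages:
        _run_stage("blocks", stage_blocks, data / "cohort.vcf",
                   results / "blocks.tsv", ld_cfg, min_call_rate)
        _run_stage(
            "blocks-subsample", stage_blocks_subsample,
            data / "cohort.vcf", results / "blocks_subsample.tsv",
            seed=seed, ld_config=ld_cfg, min_call_rate=min_call_rate,
            **subsample_keys,
        )
    if "roh" in stages:
        _run_stage("roh", stage_roh, data / "cohort.vcf", results / "roh.tsv",
                   None, roh_cfg)
    if "gwas-xref" in stages:
        _run_stage("gwas-xref", stage_gwas_xref, data / "gwas.tsv",
                   results / "audit.flags.tsv", data / "probes.tsv",
                   results / "gwas_xref.tsv")
    if "report" in stages:
        _run_stage("report", _recovery_report, data, results, summaries)

    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _recovery_report(data: Path, results: Path, summaries: dict) -> dict:
    """Compare analysis outputs against truth.json; write recovery.json."""
    truth_path = data / "truth.json"
    report: dict = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        flags_path = results / "audit.flags.tsv"
        if flags_path.exists():
            found = {
                row["probe_id"]: set() if row["flags"] == "." else set(row["flags"].split(","))
                for row in read_report_tsv(flags_path)
            }
            expected = {pid: set(fl) for pid, fl in truth["probe_flags"].items()}
            agree = sum(1 for pid in expected if found.get(pid, set()) == expected[pid])
            report["probe_flag_recovery"] = {
                "n_probes": len(expected),
                "n_exact": agree,
                "fraction": agree / len(expected) if expected else None,
            }
        venn_path = results / "concord.venn.json"
        if venn_path.exists():
            with open(venn_path) as fh:
                got = json.load(fh)
            t = truth["concordance"]
            report["concordance_recovery"] = {
                "shared_match": got["n_shared"] == len(t["shared"]),
                "unique_a_match": got["n_unique_a"] == len(t["unique_a"]),
                "unique_b_match": got["n_unique_b"] == len(t["unique_b"]),
            }
        gwas_path = results / "gwas_xref.tsv"
        if gwas_path.exists():
            affected = {
                row["study_id"] for row in read_report_tsv(gwas_path)
                if row["affected"] == "1"
            }
            report["gwas_recovery"] = {
                "expected_affected": len(truth["affected_studies"]),
                "found_affected": len(affected),
                "exact_set_match": affected == set(truth["affected_studies"]),
            }
        blocks_path = results / "blocks.tsv"
        if blocks_path.exists():
            found_blocks = {
                (int(r["start_pos"]), int(r["end_pos"]))
                for r in read_report_tsv(blocks_path)
            }
            expected_blocks = {
                (b["start_pos"], b["end_pos"]) for b in truth["block_boundaries"]
            }
            report["block_recovery"] = {
                "expected": len(expected_blocks),
                "recovered_exact": len(expected_blocks & found_blocks),
                "spurious": len(found_blocks - expected_blocks),
            }
        roh_path = results / "roh.tsv"
        if roh_path.exists():
            found_roh = {
                (r["sample"], r["chrom"], int(r["start_pos"]), int(r["end_pos"]))
                for r in read_report_tsv(roh_path)
            }
            expected_roh = {
                (r["sample"], r["chrom"], r["start_pos"], r["end_pos"])
                for r in truth["roh"]
            }
            report["roh_recovery"] = {
                "expected": len(expected_roh),
                "recovered": len(expected_roh & found_roh),
                "spurious": len(found_roh - expected_roh),
            }
    else:
        report["note"] = "no truth.json found; recovery checks skipped"
    with open(results / "recovery.json", "wt") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def render_report(run_dir: Path) -> str:
    """Human-readable per-stage summary of a finished run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json under {run_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"refaudit {manifest['tool_version']} run report", ""]
    for name in _ALL_STAGES + ("blocks-subsample",):
        entry = manifest["stages"].get(name)
        if entry is None:
            if name in manifest["config"]["stages"]:
                lines.append(f"[{name}] skipped (no output)")
            continue
        lines.append(f"[{name}] ({entry['wall_clock_s']} s)")
        for key, value in sorted(entry["summary"].items()):
            if isinstance(value, (int, float, str, bool)) or value is None:
                lines.append(f"  {key}: {value}")
        lines.append("")
    return "\n".join(lines)
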