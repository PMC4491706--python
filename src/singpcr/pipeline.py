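"""End-to-end orchestration of the four analysis stages plus simulation.

Stages: ``simulate`` (write synthetic references, designs and FASTQ),
``build-ref`` (sample-specific reference pairs from the pure samples),
``classify`` (exact-match read counting), ``quantify`` (bias correction,
relative abundance, standardization) and ``report`` (summary metrics).
Each stage writes its outputs atomically and a run manifest records the
full configuration, seed and output hashes, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import classify as _classify
from . import io
from . import quantify as q
from . import refbuild, simulate
from .models import BiasModel, CopyModel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build-ref", "classify", "quantify", "report")

PURE_COMPETITOR = "G0"
PURE_TARGET = "G10"


class PipelineError(RuntimeError):
    """Raised on missing inputs or unsatisfied stage dependencies."""


@dataclass
class RunConfig:
    """Paths, thresholds and simulation parameters for one run.

    Threshold defaults are the published analysis values: consensus depth
    >= 100, 25% position rule, 75 bp / 90% coverage alignment criterion,
    mean >= 200 reads per amplicon, >5% impurity cutoff.
    """

    out_dir: Path = Path("singpcr_run")
    seed: int = 0
    # analysis thresholds
    min_depth: int = 100
    min_pos_frac: float = 0.25
    min_aln_len: int = 75
    min_query_cov: float = 0.90
    min_mean_reads: float = 200
    max_impurity: float = 0.05
    # copy model
    target_sex: str = "female"
    competitor_sex: str = "male"
    haploid_mass_pg: float = 3.3
    # simulation scale
    n_amplicons: int = 40
    frac_x_linked: float = 0.05
    human_fractions: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    mean_depth: float = 1000.0
    depth_sd_log: float = 0.5
    bias_sd_log: float = 0.5
    error_rate: float = 0.001
    read_length: int = 100
    rep_set: str = "Rep1"
    # optional externally supplied inputs
    references: Path | None = None
    fastq_dir: Path | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("min_pos_frac", "min_query_cov", "max_impurity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        for name in ("min_depth", "min_aln_len", "min_mean_reads", "n_amplicons", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "human_fractions" in data:
            data["human_fractions"] = tuple(data["human_fractions"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["human_fractions"] = list(self.human_fractions)
        for key in ("references", "fastq_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        writer(tmp)
        tmp.replace(path)
    except Exception:
        tmp.unlink(missing_ok=True)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Path]:
    """Run the requested stages in canonical order; returns artifact paths."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        _STAGE_FUNCS[stage](config, artifacts)
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "timings_s": timings,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
            if p.is_file()
        },
    }
    _atomic_write(out / "manifest.json", lambda p: io.write_json(manifest, p))
    artifacts["manifest"] = out / "manifest.json"
    return artifacts


def _stage_simulate(config: RunConfig, artifacts: dict) -> None:
    out = config.out_dir
    specs, pairs = simulate.make_homolog_pairs(
        config.n_amplicons,
        frac_x_linked=config.frac_x_linked,
        seed=config.seed,
    )
    bias = BiasModel.lognormal(
        [p.amplicon_id for p in pairs],
        sd_log=config.bias_sd_log,
        mean_depth=config.mean_depth,
        depth_sd_log=config.depth_sd_log,
        error_rate=config.error_rate,
        seed=config.seed + 1,
    )
    designs = simulate.make_gdna_designs(
        config.human_fractions, rep_set=config.rep_set, include_pure=True
    )
    counts, truth = simulate.simulate_gdna_counts(
        pairs,
        designs,
        bias,
        human_sex=config.target_sex,
        competitor_sex=config.competitor_sex,
        seed=config.seed + 2,
    )
    fastq_dir = out / "fastq"
    files = simulate.emit_fastq(
        counts,
        pairs,
        fastq_dir,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=config.seed + 3,
    )
    _atomic_write(out / "initial_refs.fasta", lambda p: io.write_pair_fasta(pairs, p))
    _atomic_write(out / "designs.yaml", lambda p: io.write_designs(designs, p))
    _atomic_write(out / "truth.tsv", lambda p: io.write_tsv(truth, p))
    sheet = [
        {
            "sample_id": d.sample_id,
            "group": d.group,
            "file": str(files[d.sample_id]),
            "rep_set": d.rep_set,
            "spikein": 1.0 - (d.human_fraction or 0.0),
        }
        for d in designs
    ]
    _atomic_write(out / "sample_sheet.tsv", lambda p: io.write_sample_sheet(sheet, p))
    artifacts.update(
        {
            "initial_refs": out / "initial_refs.fasta",
            "designs": out / "designs.yaml",
            "truth": out / "truth.tsv",
            "sample_sheet": out / "sample_sheet.tsv",
            "fastq_dir": fastq_dir,
        }
    )


def _initial_refs_path(config: RunConfig, artifacts: dict) -> Path:
    path = artifacts.get("initial_refs") or config.references or (config.out_dir / "initial_refs.fasta")
    path = Path(path)
    if not path.exists():
        raise PipelineError(
            f"initial references not found at {path}; run the simulate stage or pass references="
        )
    return path


def _sample_sheet(config: RunConfig, artifacts: dict) -> pd.DataFrame:
    path = artifacts.get("sample_sheet") or config.out_dir / "sample_sheet.tsv"
    if not Path(path).exists():
        raise PipelineError(f"sample sheet not found at {path}")
    return io.read_sample_sheet(path)


def _stage_build_ref(config: RunConfig, artifacts: dict) -> None:
    out = config.out_dir
    sheet = _sample_sheet(config, artifacts)
    files = dict(zip(sheet["sample_id"], sheet["file"]))
    for pure in (PURE_TARGET, PURE_COMPETITOR):
        if pure not in files:
            raise PipelineError(f"pure sample {pure} missing from sample sheet")
    initial = io.read_pair_fasta(_initial_refs_path(config, artifacts))
    gene_ids = {p.amplicon_id: p.gene_id for p in initial}
    copy_classes = {p.amplicon_id: p.copy_class for p in initial}
    init_refs = {}
    for p in initial:
        init_refs[f"{p.amplicon_id}|target"] = p.target_seq
        init_refs[f"{p.amplicon_id}|competitor"] = p.competitor_seq
    pairs, rejects = refbuild.build_reference_library(
        files[PURE_TARGET],
        files[PURE_COMPETITOR],
        init_refs,
        min_aln_len=config.min_aln_len,
        min_query_cov=config.min_query_cov,
        min_pos_frac=config.min_pos_frac,
        min_depth=config.min_depth,
        gene_ids=gene_ids,
        copy_classes=copy_classes,
    )
    if not pairs:
        raise PipelineError("reference building yielded no usable pairs")
    _atomic_write(out / "references.fasta", lambda p: io.write_pair_fasta(pairs, p))
    _atomic_write(
        out / "reference_rejects.tsv",
        lambda p: io.write_tsv(pd.DataFrame(rejects, columns=["amplicon_id", "species", "reason", "depth"]), p),
    )
    artifacts["references"] = out / "references.fasta"
    artifacts["reference_rejects"] = out / "reference_rejects.tsv"


def _references_path(config: RunConfig, artifacts: dict) -> Path:
    path = artifacts.get("references") or config.references or (config.out_dir / "references.fasta")
    path = Path(path)
    if not path.exists():
        raise PipelineError(
            f"reference library not found at {path}; run build-ref first or pass references="
        )
    return path


def _stage_classify(config: RunConfig, artifacts: dict) -> None:
    out = config.out_dir
    sheet = _sample_sheet(config, artifacts)
    library = io.read_pair_fasta(_references_path(config, artifacts))
    counts, stats = _classify.count_reads(
        sheet,
        library,
        min_aln_len=config.min_aln_len,
        min_query_cov=config.min_query_cov,
    )
    _atomic_write(out / "counts.tsv", lambda p: io.write_tsv(counts, p))
    _atomic_write(out / "classify_stats.tsv", lambda p: io.write_tsv(stats, p))
    artifacts["counts"] = out / "counts.tsv"
    artifacts["classify_stats"] = out / "classify_stats.tsv"


def _stage_quantify(config: RunConfig, artifacts: dict) -> None:
    out = config.out_dir
    counts_path = artifacts.get("counts") or out / "counts.tsv"
    if not Path(counts_path).exists():
        raise PipelineError(f"counts not found at {counts_path}; run classify first")
    counts = io.read_tsv(counts_path, dtype={"sample_id": str})
    library = io.read_pair_fasta(_references_path(config, artifacts))
    copy_model = CopyModel.from_pairs(
        library,
        target_sex=config.target_sex,
        competitor_sex=config.competitor_sex,
        haploid_mass_pg=config.haploid_mass_pg,
    )
    purity = _classify.purity_check(
        counts, PURE_TARGET, PURE_COMPETITOR, max_impurity=config.max_impurity
    )
    mixture = counts[~counts["sample_id"].isin([PURE_TARGET, PURE_COMPETITOR])]
    fractions = q.compute_fractions(mixture)
    fractions = q.qc_filter(
        fractions, min_mean_reads=config.min_mean_reads, purity_flags=purity
    )
    fractions = q.correct_gdna_set(fractions)
    ra = q.to_relative_abundance(fractions, copy_model)
    quant = q.standardize(ra, standard="autosomal", copy_model=copy_model)
    cols = [
        "sample_id",
        "amplicon_id",
        "gamma_hs",
        "gamma_hs_c",
        "ra_hp",
        "stdqt",
        "qc_pass",
        "qc_reason",
    ]
    _atomic_write(out / "quant.tsv", lambda p: io.write_tsv(quant[cols], p))
    artifacts["quant"] = out / "quant.tsv"


def _stage_report(config: RunConfig, artifacts: dict) -> None:
    out = config.out_dir
    quant_path = artifacts.get("quant") or out / "quant.tsv"
    if not Path(quant_path).exists():
        raise PipelineError(f"quant table not found at {quant_path}; run quantify first")
    quant = io.read_tsv(quant_path, dtype={"sample_id": str})
    passing = quant[quant["qc_pass"] == True]  # noqa: E712
    metrics: dict = {"n_amplicons_pass": int(passing["amplicon_id"].nunique())}
    per_sample = {}
    for sample, block in passing.groupby("sample_id"):
        per_sample[sample] = {
            "cv_gamma_raw": q.cv(block["gamma_hs"]),
            "cv_gamma_corrected": q.cv(block["gamma_hs_c"]),
            "mean_stdqt": float(block["stdqt"].mean()),
        }
    metrics["per_sample"] = per_sample
    metrics["measurement_window"] = q.measurement_window(passing["ra_hp"])
    truth_path = out / "truth.tsv"
    if truth_path.exists():
        truth = io.read_tsv(truth_path, dtype={"sample_id": str})
        merged = passing.merge(truth, on=["sample_id", "amplicon_id"], how="inner")
        if not merged.empty:
            metrics["rmsd_gamma_corrected_vs_truth"] = q.rmsd(
                merged["gamma_hs_c"], merged["f_true"]
            )
    avg = q.average_stdqt(passing)
    metrics["mean_stdqt_overall"] = float(avg.mean())
    _atomic_write(out / "metrics.json", lambda p: io.write_json(metrics, p))
    artifacts["metrics"] = out / "metrics.json"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "build-ref": _stage_build_ref,
    "classify": _stage_classify,
    "quantify": _stage_quantify,
    "report": _stage_report,
}
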