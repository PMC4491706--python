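"""Synthetic data with the statistical structure of competitive PCR
amplicon sequencing against a spiked-in neighbor genome.

The generator produces homologous target/competitor amplicon pairs
(~67 bp, mostly single-nucleotide inter-species variations), gDNA
mixtures at known target-species fractions, cDNA samples with graded
competitor-gDNA spike-ins, per-amplicon multiplicative amplification
biases, log-normal per-amplicon read depths and binomial read sampling,
optionally emitting raw FASTQ so the whole pipeline can be exercised
end to end without external data.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    AUTOSOMAL,
    COMPETITOR,
    TARGET,
    X_LINKED,
    BiasModel,
    CopyModel,
    HomologPairSpec,
    MixtureDesign,
    ReferencePair,
    copies_for,
    strength_class_of_base,
)

_BASES = np.array(list("ACGT"))
_RC = str.maketrans("ACGTN", "TGCAN")

#: ISV count distribution: amplicons carry mostly single-nucleotide
#: inter-species variations.
DEFAULT_ISV_DIST: dict[int, float] = {1: 0.75, 2: 0.20, 3: 0.05}


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def make_homolog_pairs(
    n: int,
    length_mean: float = 67.0,
    length_sd: float = 10.4,
    isv_per_amplicon: Mapping[int, float] | None = None,
    frac_x_linked: float = 0.05,
    frac_isv_deficient: float = 0.0,
    primer_margin: int = 18,
    max_length: int = 100,
    loci_per_gene: int = 2,
    seed: int = 0,
) -> tuple[list[HomologPairSpec], list[ReferencePair]]:
    """Generate ``n`` homologous amplicon pairs.

    Sequences of a pair are identical except at the ISV positions, which are
    placed in the interior of the amplicon (outside the ``primer_margin``
    flanks where primers must bind both species).  Copy class (autosomal vs
    X-linked) is assigned per gene so that multiple loci of one gene share a
    chromosome.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, frac in (("frac_x_linked", frac_x_linked), ("frac_isv_deficient", frac_isv_deficient)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0,1]")
    if length_mean <= 2 * primer_margin:
        raise ValueError("length_mean must exceed twice the primer margin")
    isv_dist = dict(isv_per_amplicon or DEFAULT_ISV_DIST)
    counts = np.array(list(isv_dist.keys()))
    probs = np.array(list(isv_dist.values()), dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    min_length = 2 * primer_margin + 3
    lengths = np.clip(
        np.rint(rng.normal(length_mean, length_sd, size=n)).astype(int),
        min_length,
        max_length,
    )
    n_genes = math.ceil(n / loci_per_gene)
    gene_x = rng.random(n_genes) < frac_x_linked
    deficient = rng.random(n) < frac_isv_deficient
    n_isv = rng.choice(counts, size=n, p=probs)

    specs: list[HomologPairSpec] = []
    pairs: list[ReferencePair] = []
    for i in range(n):
        length = int(lengths[i])
        gene_idx = i // loci_per_gene
        amp_id = f"amp{i:04d}"
        gene_id = f"gene{gene_idx:03d}"
        copy_class = X_LINKED if gene_x[gene_idx] else AUTOSOMAL
        target = _BASES[rng.integers(0, 4, size=length)]
        if deficient[i]:
            seq = "".join(target)
            specs.append(
                HomologPairSpec(amp_id, gene_id, length, (), (), copy_class, isv_deficient=True)
            )
            # deliberately ISV-deficient: no ReferencePair can exist
            continue
        k = int(min(n_isv[i], length - 2 * primer_margin))
        positions = np.sort(
            rng.choice(np.arange(primer_margin, length - primer_margin), size=k, replace=False)
        )
        competitor = target.copy()
        strengths = []
        for pos in positions:
            alternatives = [b for b in "ACGT" if b != target[pos]]
            competitor[pos] = alternatives[rng.integers(0, 3)]
            strengths.append(strength_class_of_base(str(target[pos])))
        specs.append(
            HomologPairSpec(
                amp_id,
                gene_id,
                length,
                tuple(int(p) for p in positions),
                tuple(strengths),
                copy_class,
            )
        )
        pairs.append(
            ReferencePair(
                amp_id,
                "".join(target),
                "".join(competitor),
                tuple(int(p) for p in positions),
                gene_id=gene_id,
                copy_class=copy_class,
            )
        )
    return specs, pairs


def make_gdna_designs(
    fractions: Sequence[float] | None = None,
    rep_set: str = "Rep1",
    include_pure: bool = False,
) -> list[MixtureDesign]:
    """gDNA mixture series; defaults to target fractions 0.1 .. 0.9.

    With ``include_pure`` the pure competitor (G0, f=0) and pure target
    (G10, f=1) samples used for reference building and purity checks are
    prepended/appended.
    """
    if fractions is None:
        fractions = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
    designs = [
        MixtureDesign(f"G{i}", "G", human_fraction=float(f), rep_set=rep_set)
        for i, f in enumerate(fractions, start=1)
    ]
    if include_pure:
        designs = (
            [MixtureDesign("G0", "G", human_fraction=0.0, rep_set=rep_set)]
            + designs
            + [MixtureDesign("G10", "G", human_fraction=1.0, rep_set=rep_set)]
        )
    return designs


def sample_expression_profile(
    amplicon_ids: Sequence[str],
    mean_copies: float = 1500.0,
    sd_log: float = 1.2,
    seed: int = 0,
) -> dict[str, float]:
    """Log-normal true expression (target copies per unit sample).

    The default spread (sd of log = 1.2) yields relative abundances spanning
    a few-hundred-fold window, comparable to the usable 400-fold direct
    comparison range of the assay.
    """
    rng = np.random.default_rng(seed)
    meanlog = math.log(mean_copies) - 0.5 * sd_log**2
    values = rng.lognormal(meanlog, sd_log, size=len(amplicon_ids))
    return dict(zip(amplicon_ids, values))


def spike_mass_for_mean_ra(
    expression_profile: Mapping[str, float],
    mean_ra: float,
    haploid_mass_pg: float = 3.3,
) -> float:
    """Spike-in mass (ng) that sets the sample-mean relative abundance."""
    mean_expr = float(np.mean(list(expression_profile.values())))
    return mean_expr / (mean_ra * 1000.0 / haploid_mass_pg)


def make_cdna_designs(
    expression_profile: Mapping[str, float],
    spikein_masses_ng: Sequence[float],
    group: str = "F",
    rep_set: str = "Rep1",
) -> list[MixtureDesign]:
    return [
        MixtureDesign(
            f"{group}{i}",
            group,
            expression_profile=dict(expression_profile),
            spikein_mass_ng=float(m),
            rep_set=rep_set,
        )
        for i, m in enumerate(spikein_masses_ng, start=1)
    ]


def _sample_counts(
    rng: np.random.Generator,
    bias: BiasModel,
    amplicon_ids: Sequence[str],
    f_a: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (depth, target reads, expected gamma) for one sample."""
    meanlog, sdlog = bias.depth_lognormal_params
    depth = np.maximum(1, np.rint(rng.lognormal(meanlog, sdlog, size=len(amplicon_ids)))).astype(int)
    beta = np.array([bias.beta[a] for a in amplicon_ids])
    p = beta * f_a / (beta * f_a + (1.0 - f_a))
    n_target = rng.binomial(depth, p)
    return depth, n_target, p


def simulate_gdna_counts(
    pairs: Sequence[ReferencePair] | Sequence[HomologPairSpec],
    designs: Sequence[MixtureDesign],
    bias: BiasModel,
    human_sex: str = "female",
    competitor_sex: str = "male",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classified read counts for gDNA mixture samples.

    The true target molecule fraction of an amplicon follows from the mass
    fraction f and per-genome copy numbers:
    ``f_a = f*tc / (f*tc + (1-f)*cc)`` with tc/cc target/competitor copies
    per diploid genome (sex-dependent for X-linked loci).  Counts are
    binomial at the bias-distorted fraction; the returned ground truth
    carries (f_true, beta, depth, expected gamma) for recovery checks.
    """
    if not designs:
        raise ValueError("empty design list")
    if any(d.group != "G" for d in designs):
        raise ValueError("simulate_gdna_counts expects group G designs only")
    rng = np.random.default_rng(seed)
    amp_ids = [p.amplicon_id for p in pairs]
    tc = np.array([copies_for(p.copy_class, human_sex) for p in pairs], dtype=float)
    cc = np.array([copies_for(p.copy_class, competitor_sex) for p in pairs], dtype=float)

    count_rows, truth_rows = [], []
    for d in designs:
        f = d.human_fraction
        num = f * tc
        den = f * tc + (1.0 - f) * cc
        f_a = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        depth, n_target, p = _sample_counts(rng, bias, amp_ids, f_a)
        for j, amp in enumerate(amp_ids):
            count_rows.append(
                (d.sample_id, amp, int(n_target[j]), int(depth[j] - n_target[j]))
            )
            truth_rows.append(
                (d.sample_id, amp, float(f_a[j]), float(bias.beta[amp]), int(depth[j]), float(p[j]))
            )
    counts = pd.DataFrame(
        count_rows, columns=["sample_id", "amplicon_id", "n_target", "n_competitor"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "amplicon_id", "f_true", "beta", "depth", "expected_gamma"],
    )
    return counts, truth


def simulate_cdna_counts(
    pairs: Sequence[ReferencePair] | Sequence[HomologPairSpec],
    designs: Sequence[MixtureDesign],
    bias: BiasModel,
    rt_efficiency: Mapping[str, float] | None = None,
    competitor_sex: str = "male",
    haploid_mass_pg: float = 3.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classified read counts for cDNA samples with competitor gDNA spike-in.

    Target copies are expression x reverse-transcription efficiency;
    competitor copies come from the spiked mass converted to haploid genome
    equivalents (3.3 pg each) times the per-genome copy representation
    (cc/2, halving X-linked loci of a male competitor).  The returned truth
    carries the true relative abundance ``ra_true = target_copies /
    (mass_ng * copies_per_ng)`` which is copy-class independent.
    """
    if not designs:
        raise ValueError("empty design list")
    if any(d.group not in ("F", "I") for d in designs):
        raise ValueError("simulate_cdna_counts expects group F/I designs only")
    rng = np.random.default_rng(seed)
    amp_ids = [p.amplicon_id for p in pairs]
    cc = np.array([copies_for(p.copy_class, competitor_sex) for p in pairs], dtype=float)
    copies_per_ng = 1000.0 / haploid_mass_pg
    rt = rt_efficiency or {}

    count_rows, truth_rows = [], []
    for d in designs:
        if d.spikein_mass_ng < 0:
            raise ValueError("spike-in mass must be >= 0")
        h = np.array(
            [d.expression_profile.get(a, 0.0) * rt.get(a, 1.0) for a in amp_ids]
        )
        comp = d.spikein_mass_ng * copies_per_ng * cc / 2.0
        total = h + comp
        f_a = np.divide(h, total, out=np.ones_like(h), where=total > 0)
        depth, n_target, p = _sample_counts(rng, bias, amp_ids, f_a)
        ra_true = (
            h / (d.spikein_mass_ng * copies_per_ng)
            if d.spikein_mass_ng > 0
            else np.full_like(h, np.inf)
        )
        for j, amp in enumerate(amp_ids):
            count_rows.append(
                (d.sample_id, amp, int(n_target[j]), int(depth[j] - n_target[j]))
            )
            truth_rows.append(
                (
                    d.sample_id,
                    amp,
                    float(f_a[j]),
                    float(bias.beta[amp]),
                    int(depth[j]),
                    float(p[j]),
                    float(ra_true[j]),
                )
            )
    counts = pd.DataFrame(
        count_rows, columns=["sample_id", "amplicon_id", "n_target", "n_competitor"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id",
            "amplicon_id",
            "f_true",
            "beta",
            "depth",
            "expected_gamma",
            "ra_true",
        ],
    )
    return counts, truth


def emit_fastq(
    counts: pd.DataFrame,
    pairs: Sequence[ReferencePair],
    out_dir: str | Path,
    read_length: int = 100,
    error_rate: float = 0.0,
    revcomp_frac: float = 0.5,
    shuffle: bool = True,
    seed: int = 0,
) -> dict[str, Path]:
    """Turn classified counts into single-end FASTQ files, one per sample.

    Each counted molecule becomes one read: the amplicon sequence (truncated
    to ``read_length`` if longer) padded to full read length with random
    adaptor-like bases, optionally reverse-complemented, with per-base
    substitution errors at ``error_rate``.  Quality is a constant Phred+33
    'I' (Q40).  Returns sample_id -> written path.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0,1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seqs = {p.amplicon_id: (p.target_seq, p.competitor_seq) for p in pairs}
    written: dict[str, Path] = {}
    for sample_id, block in counts.groupby("sample_id", sort=True):
        reads: list[str] = []
        for row in block.itertuples(index=False):
            if row.amplicon_id not in seqs:
                raise KeyError(f"no reference pair for amplicon {row.amplicon_id!r}")
            tgt, comp = seqs[row.amplicon_id]
            for species_seq, n in ((tgt, row.n_target), (comp, row.n_competitor)):
                core = species_seq[:read_length]
                pad = read_length - len(core)
                for _ in range(int(n)):
                    if pad:
                        tail = "".join(_BASES[rng.integers(0, 4, size=pad)])
                        read = core + tail
                    else:
                        read = core
                    if error_rate > 0.0:
                        arr = np.frombuffer(read.encode(), dtype="S1").copy()
                        hits = np.nonzero(rng.random(read_length) < error_rate)[0]
                        for pos in hits:
                            current = arr[pos].decode()
                            options = [b for b in "ACGT" if b != current]
                            arr[pos] = options[rng.integers(0, len(options))].encode()
                        read = b"".join(arr).decode()
                    if rng.random() < revcomp_frac:
                        read = reverse_complement(read)
                    reads.append(read)
        if shuffle:
            rng.shuffle(reads)
        path = out_dir / f"{sample_id}.fastq"
        qual = "I" * read_length
        with open(path, "w") as fh:
            for i, read in enumerate(reads):
                fh.write(f"@{sample_id}:{i}\n{read}\n+\n{qual}\n")
        written[str(sample_id)] = path
    return written


def expected_stdqt_gdna(
    pairs: Sequence[ReferencePair] | Sequence[HomologPairSpec],
    copy_model: CopyModel,
) -> pd.Series:
    """Expected standardized quantity of each amplicon in a gDNA mixture
    series processed with multi-reference bias correction.

    Any odds factor that is constant for an amplicon across the mixture
    series — the amplification bias, but equally a target-side copy ratio
    such as the 2x of an X-linked locus in a female donor — is
    indistinguishable from bias and is absorbed by the correction, which
    maps every amplicon's corrected fraction onto the sample-consensus
    fraction.  The corrected odds therefore equal the genome-equivalent
    odds f/(1-f), the relative abundance becomes ``f/(1-f) * cc/2`` and the
    standardized quantity ``cc/2`` (cc = competitor copies per diploid
    genome): 1 for autosomal amplicons, 1/2 for X-linked ones against a
    male competitor, independent of the donor's sex.
    """
    return pd.Series(
        {p.amplicon_id: copy_model.competitor_copies(p.amplicon_id) / 2.0 for p in pairs},
        name="expected_stdqt",
    )


def expected_stdqt_cdna(
    expression_profile: Mapping[str, float],
    rt_efficiency: Mapping[str, float] | None = None,
) -> pd.Series:
    """Expected standardized quantity (standard = all amplicons) of cDNA
    amplicons: sampled copies relative to their mean, spike-in independent."""
    rt = rt_efficiency or {}
    h = pd.Series(
        {a: v * rt.get(a, 1.0) for a, v in expression_profile.items()}, dtype=float
    )
    return (h / h.mean()).rename("expected_stdqt")
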