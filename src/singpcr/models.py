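"""Core data structures shared across all pipeline stages.

The central objects of competitive PCR amplicon sequencing against a spiked-in
neighbor genome are homologous amplicon *pairs*: one sequence from the target
species (e.g. human) and one from the competitor species (e.g. orangutan),
identical except at a handful of inter-species variation (ISV) positions that
let a sequencing read be attributed to its species of origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

AUTOSOMAL = "autosomal"
X_LINKED = "x_linked"

TARGET = "target"
COMPETITOR = "competitor"

#: ISV strength classes: the target-species variant nucleotide forms weak
#: (A/T, two hydrogen bonds) or strong (G/C, three hydrogen bonds) base pairs.
WEAK = "W"
STRONG = "S"

_WEAK_BASES = frozenset("AT")


def copies_for(copy_class: str, sex: str) -> int:
    """Copies of a locus per diploid genome: autosomes carry 2 regardless of
    sex; X-linked loci carry 1 in males and 2 in females."""
    if copy_class == AUTOSOMAL:
        return 2
    if copy_class == X_LINKED:
        return 1 if sex == "male" else 2
    raise ValueError(f"unknown copy class {copy_class!r}")


@dataclass(frozen=True)
class HomologPairSpec:
    """Blueprint of one simulated homologous amplicon pair."""

    amplicon_id: str
    gene_id: str
    length: int
    isv_positions: tuple[int, ...]
    isv_strength_class: tuple[str, ...]
    copy_class: str = AUTOSOMAL
    isv_deficient: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("amplicon length must be positive")
        if not self.isv_deficient and not self.isv_positions:
            raise ValueError("non-deficient pair must carry >=1 ISV")
        if any(p < 0 or p >= self.length for p in self.isv_positions):
            raise ValueError("ISV offset outside amplicon")
        if len(self.isv_strength_class) != len(self.isv_positions):
            raise ValueError("one strength class per ISV required")

    @property
    def strength_class(self) -> str | None:
        """Amplicon-level W/S label: majority class of its ISVs, ties to S."""
        if not self.isv_positions:
            return None
        n_s = sum(c == STRONG for c in self.isv_strength_class)
        return STRONG if 2 * n_s >= len(self.isv_strength_class) else WEAK


@dataclass(frozen=True)
class ReferencePair:
    """A species-discriminating reference pair for one amplicon.

    ``isv_positions`` are 0-based offsets at which the two equal-length
    sequences differ.
    """

    amplicon_id: str
    target_seq: str
    competitor_seq: str
    isv_positions: tuple[int, ...]
    gene_id: str = ""
    copy_class: str = AUTOSOMAL

    def __post_init__(self) -> None:
        if len(self.target_seq) != len(self.competitor_seq):
            raise ValueError("paired sequences must have equal length")
        diffs = tuple(
            i for i, (a, b) in enumerate(zip(self.target_seq, self.competitor_seq)) if a != b
        )
        if diffs != tuple(self.isv_positions):
            raise ValueError("isv_positions inconsistent with sequence difference")
        if not diffs:
            raise ValueError("reference pair must differ at >=1 position")

    @classmethod
    def from_sequences(
        cls,
        amplicon_id: str,
        target_seq: str,
        competitor_seq: str,
        gene_id: str = "",
        copy_class: str = AUTOSOMAL,
    ) -> "ReferencePair":
        diffs = tuple(
            i for i, (a, b) in enumerate(zip(target_seq, competitor_seq)) if a != b
        )
        return cls(amplicon_id, target_seq, competitor_seq, diffs, gene_id, copy_class)

    def seq(self, species: str) -> str:
        if species == TARGET:
            return self.target_seq
        if species == COMPETITOR:
            return self.competitor_seq
        raise ValueError(f"unknown species {species!r}")

    def __len__(self) -> int:
        return len(self.target_seq)


@dataclass(frozen=True)
class MixtureDesign:
    """Ground-truth composition of one sample.

    Group ``G`` samples are gDNA mixtures defined by the mass fraction of
    target-species gDNA (``human_fraction``).  Groups ``F``/``I`` are cDNA
    samples defined by a per-amplicon expression profile (true target copies
    per unit sample) plus the mass of spiked-in competitor gDNA.
    """

    sample_id: str
    group: str
    human_fraction: float | None = None
    expression_profile: Mapping[str, float] | None = None
    spikein_mass_ng: float | None = None
    rep_set: str = "Rep1"

    def __post_init__(self) -> None:
        if self.group == "G":
            if self.human_fraction is None or not 0.0 <= self.human_fraction <= 1.0:
                raise ValueError("group G sample needs human_fraction in [0,1]")
        elif self.group in ("F", "I"):
            if self.expression_profile is None or self.spikein_mass_ng is None:
                raise ValueError("group F/I sample needs expression_profile and spikein_mass_ng")
            if self.spikein_mass_ng < 0:
                raise ValueError("spike-in mass must be >= 0")
        else:
            raise ValueError(f"unknown sample group {self.group!r}")


@dataclass
class BiasModel:
    """Per-amplicon multiplicative amplification bias plus sampling noise.

    ``beta`` multiplies the target:competitor odds once: with a true target
    molecule fraction f the expected observed fraction is
    ``gamma = beta*f / (beta*f + 1 - f)``.  Read depth per amplicon is drawn
    log-normally; reads are then a binomial sample at the biased fraction.
    """

    beta: Mapping[str, float]
    depth_lognormal_params: tuple[float, float] = (math.log(5000.0) - 0.125, 0.5)
    substitution_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.beta.values()):
            raise ValueError("bias factors must be positive")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution error rate must be in [0,1)")

    @staticmethod
    def depth_params(mean_depth: float, sd_log: float) -> tuple[float, float]:
        """(meanlog, sdlog) of a log-normal with the requested arithmetic mean."""
        return (math.log(mean_depth) - 0.5 * sd_log**2, sd_log)

    @classmethod
    def constant(
        cls,
        amplicon_ids: Sequence[str],
        value: float = 1.0,
        mean_depth: float = 5000.0,
        depth_sd_log: float = 0.5,
        error_rate: float = 0.0,
    ) -> "BiasModel":
        return cls(
            beta={a: value for a in amplicon_ids},
            depth_lognormal_params=cls.depth_params(mean_depth, depth_sd_log),
            substitution_error_rate=error_rate,
        )

    @classmethod
    def lognormal(
        cls,
        amplicon_ids: Sequence[str],
        sd_log: float = 0.5,
        mean_depth: float = 5000.0,
        depth_sd_log: float = 0.5,
        error_rate: float = 0.0,
        strength_classes: Mapping[str, str] | None = None,
        strength_log_shift: float = 0.0,
        seed: int = 0,
    ) -> "BiasModel":
        """Draw log-symmetric biases (median beta = 1).

        When ``strength_classes`` maps amplicons to W/S and
        ``strength_log_shift`` > 0, S-class amplicons receive +shift/2 and
        W-class amplicons -shift/2 on the log scale, reproducing preferential
        enrichment of variants forming strong (G/C) hydrogen bonds.
        """
        rng = np.random.default_rng(seed)
        log_beta = rng.normal(0.0, sd_log, size=len(amplicon_ids))
        if strength_classes is not None and strength_log_shift:
            shift = np.array(
                [
                    0.5 * strength_log_shift
                    if strength_classes.get(a) == STRONG
                    else -0.5 * strength_log_shift
                    for a in amplicon_ids
                ]
            )
            log_beta = log_beta + shift
        return cls(
            beta=dict(zip(amplicon_ids, np.exp(log_beta))),
            depth_lognormal_params=cls.depth_params(mean_depth, depth_sd_log),
            substitution_error_rate=error_rate,
        )

    def expected_gamma(self, amplicon_id: str, f_a: float) -> float:
        b = self.beta[amplicon_id]
        return b * f_a / (b * f_a + (1.0 - f_a))


@dataclass
class CopyModel:
    """Per-amplicon copy-number accounting for both genomes.

    The competitor genome (a male neighbor-species gDNA in the original
    design) carries 2 copies of autosomal and 1 copy of X-linked amplicons
    per diploid genome.  ``haploid_mass_pg`` converts spike-in mass to genome
    equivalents (3.3 pg per haploid genome).
    """

    copy_class: Mapping[str, str] = field(default_factory=dict)
    target_sex: str = "female"
    competitor_sex: str = "male"
    haploid_mass_pg: float = 3.3

    def __post_init__(self) -> None:
        if self.haploid_mass_pg <= 0:
            raise ValueError("haploid genome mass must be positive")

    def class_of(self, amplicon_id: str) -> str:
        return self.copy_class.get(amplicon_id, AUTOSOMAL)

    def target_copies(self, amplicon_id: str) -> int:
        return copies_for(self.class_of(amplicon_id), self.target_sex)

    def competitor_copies(self, amplicon_id: str) -> int:
        return copies_for(self.class_of(amplicon_id), self.competitor_sex)

    @property
    def copies_per_ng(self) -> float:
        """Haploid genome equivalents per ng of gDNA (~303 for 3.3 pg)."""
        return 1000.0 / self.haploid_mass_pg

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[ReferencePair] | Sequence[HomologPairSpec],
        target_sex: str = "female",
        competitor_sex: str = "male",
        haploid_mass_pg: float = 3.3,
    ) -> "CopyModel":
        return cls(
            copy_class={p.amplicon_id: p.copy_class for p in pairs},
            target_sex=target_sex,
            competitor_sex=competitor_sex,
            haploid_mass_pg=haploid_mass_pg,
        )


@dataclass
class ConsensusCall:
    """Result of consensus building over one amplicon's pure-sample reads."""

    amplicon_id: str
    species: str
    sequence: str | None
    depth: int
    monomorphic: bool
    retained: bool
    reason: str | None = None


class Assignment(NamedTuple):
    """Outcome of classifying one read."""

    status: str  # "assigned" | "ambiguous" | "unassigned"
    amplicon_id: str | None = None
    species: str | None = None


def strength_class_of_base(base: str) -> str:
    """W for A/T target variants, S for G/C."""
    return WEAK if base in _WEAK_BASES else STRONG
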