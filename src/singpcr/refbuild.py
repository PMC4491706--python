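"""Build sample-specific, species-discriminating reference pairs from
pure-sample reads.

Workflow: group reads of a pure target-species sample (and, separately, a
pure competitor-species sample) by amplicon against initial references,
build a per-amplicon consensus from a gapless pileup, then pair the two
species' consensuses and record their ISV positions.  Amplicons whose
consensuses are identical across species are ISV-deficient and unusable for
species attribution; amplicons missing one species are dropped as not
amplified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from . import io
from .models import COMPETITOR, TARGET, ConsensusCall, ReferencePair
from .simulate import reverse_complement

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def required_match_length(ref_len: int, min_aln_len: int = 75, min_query_cov: float = 0.90) -> int:
    """Effective minimum matched length: an aligned stretch of at least
    ``min_aln_len`` bases *or* covering ``min_query_cov`` of the reference —
    i.e. min(75, ceil(0.9 * reference length)) with the defaults."""
    return min(min_aln_len, math.ceil(min_query_cov * ref_len))


def _as_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        return io.iter_fastq(reads)
    return ((rid, seq) for rid, seq in reads)


def _as_refs(initial_refs) -> dict[str, str]:
    if isinstance(initial_refs, (str, Path)):
        return io.read_fasta(initial_refs)
    return dict(initial_refs)


def group_pure_reads(
    reads,
    initial_refs,
    min_aln_len: int = 75,
    min_query_cov: float = 0.90,
    max_divergence: float = 0.10,
    seed_k: int = 21,
) -> tuple[dict[str, list[tuple[int, str]]], dict[str, int]]:
    """Assign pure-sample reads to amplicons against initial references.

    ``reads`` is a FASTQ path or an iterable of (id, sequence); initial
    references a FASTA path or mapping name -> sequence, where the amplicon
    id is the name up to an optional ``|species`` suffix.  A read is
    collected for an amplicon when an initial reference aligns into it (or
    it aligns into the reference) over the required length with at most
    ``max_divergence`` mismatches; reads matching two or more amplicons are
    discarded as ambiguous, never assigned to the best hit.

    Returns ``(groups, stats)`` where ``groups`` maps amplicon id to a
    gapless pileup of (reference offset, oriented segment) entries.
    """
    refs = _as_refs(initial_refs)
    if not refs:
        raise ValueError("initial references must be non-empty")
    ref_list = []  # (name, amp_id, seq)
    seen_names = set()
    for name, seq in refs.items():
        if name in seen_names:
            raise ValueError(f"duplicate reference id {name!r}")
        seen_names.add(name)
        ref_list.append((name, name.split("|")[0], seq.upper()))

    # seed index over short k-mers of each reference (forward orientation);
    # the reverse strand is handled by also scanning the reverse-complemented read
    index: dict[str, set[int]] = {}
    for ri, (_, _, seq) in enumerate(ref_list):
        for i in range(0, max(len(seq) - seed_k, 0) + 1):
            index.setdefault(seq[i : i + seed_k], set()).add(ri)

    groups: dict[str, list[tuple[int, str]]] = {}
    stats = {"total": 0, "assigned": 0, "ambiguous": 0, "unassigned": 0}
    n_reads = 0
    for _, read in _as_reads(reads):
        n_reads += 1
        stats["total"] += 1
        read = read.upper()
        rc = reverse_complement(read)
        candidates: set[tuple[int, int]] = set()  # (ref index, orientation)
        for orient, oread in enumerate((read, rc)):
            span = max(len(oread) - seed_k, 0)
            positions = set(range(0, span + 1, seed_k))
            positions.add(span)
            for p in positions:
                for ri in index.get(oread[p : p + seed_k], ()):
                    candidates.add((ri, orient))
        hits: dict[str, tuple[int, str]] = {}
        conflict = False
        for ri, orient in sorted(candidates):
            name, amp_id, seq = ref_list[ri]
            oread = read if orient == 0 else rc
            placement = _place(oread, seq, min_aln_len, min_query_cov, max_divergence)
            if placement is None:
                continue
            if amp_id in hits:
                continue  # both species of one amplicon: same amplicon, fine
            if hits:
                conflict = True
            hits[amp_id] = placement
        if conflict or len(hits) > 1:
            stats["ambiguous"] += 1
        elif len(hits) == 1:
            (amp_id, placement), = hits.items()
            groups.setdefault(amp_id, []).append(placement)
            stats["assigned"] += 1
        else:
            stats["unassigned"] += 1
    if n_reads == 0:
        logger.warning("no reads supplied to group_pure_reads; empty grouping returned")
    return groups, stats


def _place(
    oread: str,
    ref: str,
    min_aln_len: int,
    min_query_cov: float,
    max_divergence: float,
) -> tuple[int, str] | None:
    """Gapless placement of a read against one reference.

    Returns (reference offset, read segment in reference orientation) or
    None.  Full containment of the reference in the read is tried first
    (exact, then edlib infix); a read shorter than the reference is instead
    aligned into the reference, provided it still satisfies the matched
    length rule.  Alignments whose span differs from the query length
    (i.e. with indels) are rejected: the pileup is gapless.
    """
    lmin = required_match_length(len(ref), min_aln_len, min_query_cov)
    pos = oread.find(ref)
    if pos >= 0:
        return 0, ref
    max_ed = int(max_divergence * len(ref))
    if len(oread) >= len(ref):
        res = edlib.align(ref, oread, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] >= 0:
            start, end = res["locations"][0]
            segment = oread[start : end + 1]
            if len(segment) == len(ref):
                return 0, segment
        return None
    # partial read inside the reference
    if len(oread) < lmin:
        return None
    max_ed = int(max_divergence * len(oread))
    res = edlib.align(oread, ref, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] >= 0:
        start, end = res["locations"][0]
        if end - start + 1 == len(oread):
            return start, oread
    return None


def build_consensus(
    pileup: Sequence[tuple[int, str]] | Sequence[str],
    amplicon_id: str = "",
    species: str = TARGET,
    min_pos_frac: float = 0.25,
    min_depth: int = 100,
    ref_length: int | None = None,
) -> ConsensusCall:
    """Consensus over a gapless pileup of one amplicon's reads.

    At each position, bases reaching ``min_pos_frac`` of the reads covering
    that position are retained; more than one retained base at any position
    marks the sequence heterozygous and the call is rejected, as is any
    call with fewer than ``min_depth`` reads.
    """
    entries = [(0, p) if isinstance(p, str) else (int(p[0]), p[1]) for p in pileup]
    depth = len(entries)
    if depth == 0:
        return ConsensusCall(amplicon_id, species, None, 0, False, False, "no_reads")
    length = ref_length or max(off + len(seq) for off, seq in entries)
    counts = np.zeros((length, 4), dtype=np.int64)
    for off, seq in entries:
        for i, base in enumerate(seq):
            j = _BASE_INDEX.get(base)
            if j is not None and off + i < length:
                counts[off + i, j] += 1
    coverage = counts.sum(axis=1)
    if (coverage == 0).any():
        return ConsensusCall(
            amplicon_id, species, None, depth, False, False, "uncovered_positions"
        )
    retained_per_pos = (counts >= np.ceil(min_pos_frac * coverage)[:, None]).sum(axis=1)
    monomorphic = bool((retained_per_pos <= 1).all())
    sequence = "".join("ACGT"[j] for j in counts.argmax(axis=1))
    if depth < min_depth:
        return ConsensusCall(
            amplicon_id, species, sequence, depth, monomorphic, False, "low_depth"
        )
    if not monomorphic:
        return ConsensusCall(
            amplicon_id, species, sequence, depth, False, False, "heterozygous"
        )
    return ConsensusCall(amplicon_id, species, sequence, depth, True, True, None)


def pair_references(
    target_calls: Mapping[str, ConsensusCall],
    competitor_calls: Mapping[str, ConsensusCall],
    gene_ids: Mapping[str, str] | None = None,
    copy_classes: Mapping[str, str] | None = None,
) -> tuple[list[ReferencePair], list[dict]]:
    """Pair retained per-species consensuses into reference pairs.

    Returns (pairs, dropped) where dropped rows record the amplicon and the
    rejection reason: ``not_amplified`` (one species missing or not
    retained), ``length_mismatch`` (cannot be paired end-to-end gaplessly)
    or ``isv_deficient`` (identical sequences, species indistinguishable).
    """
    gene_ids = gene_ids or {}
    copy_classes = copy_classes or {}
    pairs: list[ReferencePair] = []
    dropped: list[dict] = []
    for amp in sorted(set(target_calls) | set(competitor_calls)):
        t = target_calls.get(amp)
        c = competitor_calls.get(amp)
        if t is None or c is None or not t.retained or not c.retained:
            reasons = []
            for species, call in ((TARGET, t), (COMPETITOR, c)):
                if call is None:
                    reasons.append(f"{species}:missing")
                elif not call.retained:
                    reasons.append(f"{species}:{call.reason}")
            dropped.append(
                {"amplicon_id": amp, "reason": "not_amplified", "detail": ";".join(reasons)}
            )
            continue
        if len(t.sequence) != len(c.sequence):
            dropped.append(
                {"amplicon_id": amp, "reason": "length_mismatch", "detail": ""}
            )
            continue
        if t.sequence == c.sequence:
            dropped.append({"amplicon_id": amp, "reason": "isv_deficient", "detail": ""})
            continue
        pairs.append(
            ReferencePair.from_sequences(
                amp,
                t.sequence,
                c.sequence,
                gene_id=gene_ids.get(amp, ""),
                copy_class=copy_classes.get(amp, "autosomal"),
            )
        )
    return pairs, dropped


@dataclass(frozen=True)
class IsvWindow:
    """A candidate amplicon window on a pairwise alignment of long
    homologous sequences: identical primer-binding flanks enclosing an
    interior with at least one ISV."""

    start: int
    end: int  # half-open, alignment columns
    isv_positions: tuple[int, ...]

    @property
    def n_isv(self) -> int:
        return len(self.isv_positions)

    @property
    def length(self) -> int:
        return self.end - self.start


def find_isv_windows(
    target_aln: str,
    competitor_aln: str,
    window_len_range: tuple[int, int] = (50, 90),
    flank_len: int = 18,
    max_flank_mismatch: int = 0,
    preferred_len: int = 67,
) -> list[IsvWindow]:
    """Scan a pairwise alignment for amplicon-sized windows whose two
    flanks of ``flank_len`` columns match across species (at most
    ``max_flank_mismatch`` mismatching columns in total, gaps counting as
    mismatches) and whose interior carries >=1 ISV and no indel.

    Candidates are ranked by fewest interior ISVs, then by closeness of the
    window length to ``preferred_len``, then by position.
    """
    if len(target_aln) != len(competitor_aln):
        raise ValueError("alignment rows must have equal length")
    lo, hi = window_len_range
    if lo < 2 * flank_len + 1:
        raise ValueError("window length must exceed twice the flank length")
    t = target_aln.upper()
    c = competitor_aln.upper()
    n = len(t)
    gap = np.array([a == "-" or b == "-" for a, b in zip(t, c)])
    mismatch = np.array(
        [a != b and a != "-" and b != "-" for a, b in zip(t, c)]
    )
    bad_flank = (gap | mismatch).astype(int)
    cum_bad = np.concatenate([[0], np.cumsum(bad_flank)])
    cum_gap = np.concatenate([[0], np.cumsum(gap.astype(int))])
    cum_isv = np.concatenate([[0], np.cumsum(mismatch.astype(int))])

    windows: list[IsvWindow] = []
    for start in range(0, n - lo + 1):
        for length in range(lo, min(hi, n - start) + 1):
            end = start + length
            i0, i1 = start + flank_len, end - flank_len
            flank_bad = (cum_bad[i0] - cum_bad[start]) + (cum_bad[end] - cum_bad[i1])
            if flank_bad > max_flank_mismatch:
                continue
            if cum_gap[i1] - cum_gap[i0]:
                continue  # indel ISVs are out of scope
            n_isv = cum_isv[i1] - cum_isv[i0]
            if n_isv < 1:
                continue
            isvs = tuple(
                int(p) for p in np.nonzero(mismatch[i0:i1])[0] + i0
            )
            windows.append(IsvWindow(start, end, isvs))
    windows.sort(key=lambda w: (w.n_isv, abs(w.length - preferred_len), w.start))
    return windows


def build_reference_library(
    pure_target_reads,
    pure_competitor_reads,
    initial_refs,
    min_aln_len: int = 75,
    min_query_cov: float = 0.90,
    min_pos_frac: float = 0.25,
    min_depth: int = 100,
    gene_ids: Mapping[str, str] | None = None,
    copy_classes: Mapping[str, str] | None = None,
) -> tuple[list[ReferencePair], list[dict]]:
    """End-to-end reference construction from the two pure samples.

    Convenience wrapper: group each pure sample's reads, build per-species
    consensuses and pair them.  Returns (pairs, rejection report rows).
    """
    refs = _as_refs(initial_refs)
    ref_len = {name.split("|")[0]: len(seq) for name, seq in refs.items()}
    calls: dict[str, dict[str, ConsensusCall]] = {TARGET: {}, COMPETITOR: {}}
    rejects: list[dict] = []
    for species, reads in ((TARGET, pure_target_reads), (COMPETITOR, pure_competitor_reads)):
        groups, _ = group_pure_reads(reads, refs, min_aln_len, min_query_cov)
        for amp, pileup in groups.items():
            call = build_consensus(
                pileup,
                amp,
                species,
                min_pos_frac=min_pos_frac,
                min_depth=min_depth,
                ref_length=ref_len.get(amp),
            )
            calls[species][amp] = call
            if not call.retained:
                rejects.append(
                    {
                        "amplicon_id": amp,
                        "species": species,
                        "reason": call.reason,
                        "depth": call.depth,
                    }
                )
    pairs, dropped = pair_references(
        calls[TARGET], calls[COMPETITOR], gene_ids=gene_ids, copy_classes=copy_classes
    )
    for row in dropped:
        rejects.append(
            {
                "amplicon_id": row["amplicon_id"],
                "species": "pair",
                "reason": row["reason"],
                "depth": "",
            }
        )
    return pairs, rejects
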