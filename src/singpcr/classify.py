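"""Assign mixed-sample reads to (amplicon, species) under a strict
100%-identity criterion and produce the per-sample count matrix.

A read is attributed to a reference sequence only when it contains an
*exact* stretch of that sequence of at least 75 bp or covering at least 90%
of the reference (whichever is smaller for short amplicons), on either
strand.  Species attribution additionally requires that at least one
inter-species variation (ISV) position lies inside the matched stretch: a
read matching both species of an amplicon outside the ISVs cannot be
discriminated and is left unassigned.  A read satisfying the rule for two
or more different amplicons is discarded as ambiguous, never given to the
best hit.

Matching is an exhaustive exact substring search — references are short,
so this reproduces the strict-identity alignment contract without an
external aligner.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io
from .models import COMPETITOR, TARGET, Assignment, ReferencePair
from .refbuild import required_match_length
from .simulate import reverse_complement

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


class AmpliconClassifier:
    """Exact-match read classifier over a paired reference library.

    A short k-mer prefilter proposes candidate references; candidates are
    then verified by exhaustive exact substring matching with maximal
    extension, so the prefilter never changes the outcome, only the cost.
    """

    def __init__(
        self,
        library: Sequence[ReferencePair],
        min_aln_len: int = 75,
        min_query_cov: float = 0.90,
        seed_k: int = 21,
    ):
        if not library:
            raise ValueError("reference library must be non-empty")
        ids = [p.amplicon_id for p in library]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate amplicon ids in library")
        self.min_aln_len = min_aln_len
        self.min_query_cov = min_query_cov
        self.seed_k = seed_k
        self._entries: list[tuple[str, str, str, int, frozenset[int]]] = []
        # (amplicon_id, species, sequence, required length, ISV set)
        self._index: dict[str, set[int]] = {}
        for pair in library:
            isvs = frozenset(pair.isv_positions)
            for species in (TARGET, COMPETITOR):
                seq = pair.seq(species)
                lmin = required_match_length(len(seq), min_aln_len, min_query_cov)
                ei = len(self._entries)
                self._entries.append((pair.amplicon_id, species, seq, lmin, isvs))
                for i in range(0, max(len(seq) - seed_k, 0) + 1):
                    self._index.setdefault(seq[i : i + seed_k], set()).add(ei)
        min_lmin = min(e[3] for e in self._entries)
        if min_lmin < seed_k:
            raise ValueError(
                "required match length shorter than prefilter k-mer; lower seed_k"
            )
        # any qualifying exact stretch (>= min_lmin) contains an indexed
        # k-mer starting within every (min_lmin - k + 1)-wide interval, so
        # scanning the read at this stride cannot miss a qualifying match
        self._stride = max(1, min_lmin - seed_k + 1)

    def assign(self, read: str) -> Assignment:
        read = read.upper()
        if len(read) < self.seed_k:
            return Assignment(UNASSIGNED)
        oriented = (read, reverse_complement(read))
        candidates: set[tuple[int, int]] = set()
        for orient, oread in enumerate(oriented):
            span = len(oread) - self.seed_k
            positions = list(range(0, span + 1, self._stride))
            if positions[-1] != span:
                positions.append(span)
            for p in positions:
                for ei in self._index.get(oread[p : p + self.seed_k], ()):
                    candidates.add((ei, orient))
        if not candidates:
            return Assignment(UNASSIGNED)
        matched: dict[str, dict[str, bool]] = {}  # amp -> species -> isv hit
        for ei, orient in sorted(candidates):
            amp, species, seq, lmin, isvs = self._entries[ei]
            hit = _exact_match(oriented[orient], seq, lmin, isvs)
            if hit is None:
                continue
            d = matched.setdefault(amp, {})
            d[species] = d.get(species, False) or hit
        if not matched:
            return Assignment(UNASSIGNED)
        if len(matched) > 1:
            return Assignment(AMBIGUOUS)
        (amp, species_hits), = matched.items()
        discriminating = [s for s, isv_hit in species_hits.items() if isv_hit]
        if len(discriminating) == 1:
            return Assignment(ASSIGNED, amp, discriminating[0])
        return Assignment(UNASSIGNED)


def _exact_match(
    read: str, seq: str, lmin: int, isvs: frozenset[int]
) -> bool | None:
    """Does ``read`` contain an exact stretch of ``seq`` of length >= lmin?

    Returns None for no qualifying match, otherwise whether some qualifying
    maximal stretch covers an ISV position.
    """
    if seq in read:
        return bool(isvs)
    n = len(seq)
    found = None
    checked: list[tuple[int, int]] = []
    for i in range(0, n - lmin + 1):
        if any(s0 <= i and i + lmin <= s1 for s0, s1 in checked):
            continue
        p = read.find(seq[i : i + lmin])
        if p < 0:
            continue
        # maximal gapless extension of the seed hit
        s0, s1 = i, i + lmin
        r0 = p
        while s0 > 0 and r0 > 0 and seq[s0 - 1] == read[r0 - 1]:
            s0 -= 1
            r0 -= 1
        r1 = p + lmin
        while s1 < n and r1 < len(read) and seq[s1] == read[r1]:
            s1 += 1
            r1 += 1
        checked.append((s0, s1))
        found = False if found is None else found
        if any(s0 <= v < s1 for v in isvs):
            return True
    return found


def assign_read(
    read: str,
    library: Sequence[ReferencePair],
    min_aln_len: int = 75,
    min_query_cov: float = 0.90,
) -> Assignment:
    """One-shot convenience wrapper around :class:`AmpliconClassifier`."""
    return AmpliconClassifier(library, min_aln_len, min_query_cov).assign(read)


def count_reads(
    samples: Mapping[str, str | Path] | pd.DataFrame,
    library: Sequence[ReferencePair],
    min_aln_len: int = 75,
    min_query_cov: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample's reads and tally per-amplicon species counts.

    ``samples`` maps sample_id -> FASTQ path (or is a sample-sheet frame
    with ``sample_id`` and ``file`` columns).  Returns ``(counts, stats)``:
    one counts row per (sample, library amplicon) including zero rows, and
    per-sample totals partitioned into assigned / ambiguous / unassigned.
    """
    if isinstance(samples, pd.DataFrame):
        sample_files = dict(zip(samples["sample_id"].astype(str), samples["file"]))
    else:
        sample_files = {str(k): v for k, v in samples.items()}
    clf = AmpliconClassifier(library, min_aln_len, min_query_cov)
    amp_ids = [p.amplicon_id for p in library]
    count_rows, stat_rows = [], []
    for sample_id, path in sample_files.items():
        tallies = {a: [0, 0] for a in amp_ids}
        total = ambiguous = unassigned = 0
        for _, seq in _read_source(path):
            total += 1
            res = clf.assign(seq)
            if res.status == ASSIGNED:
                tallies[res.amplicon_id][0 if res.species == TARGET else 1] += 1
            elif res.status == AMBIGUOUS:
                ambiguous += 1
            else:
                unassigned += 1
        assigned = total - ambiguous - unassigned
        if total == 0:
            logger.warning("sample %s: empty FASTQ", sample_id)
        else:
            logger.info(
                "sample %s: %d/%d reads assigned (%.1f%%)",
                sample_id,
                assigned,
                total,
                100.0 * assigned / total,
            )
        for amp in amp_ids:
            n_t, n_c = tallies[amp]
            count_rows.append((sample_id, amp, n_t, n_c))
        stat_rows.append(
            {
                "sample_id": sample_id,
                "total_reads": total,
                "assigned_reads": assigned,
                "assigned_fraction": assigned / total if total else float("nan"),
                "ambiguous": ambiguous,
                "unassigned": unassigned,
            }
        )
    counts = pd.DataFrame(
        count_rows, columns=["sample_id", "amplicon_id", "n_target", "n_competitor"]
    )
    stats = pd.DataFrame(stat_rows)
    return counts, stats


def _read_source(path) -> Iterable[tuple[str, str]]:
    if isinstance(path, (str, Path)):
        return io.iter_fastq(path)
    return path


def purity_check(
    counts: pd.DataFrame,
    pure_target_sample: str,
    pure_competitor_sample: str,
    max_impurity: float = 0.05,
) -> pd.DataFrame:
    """Flag amplicons with wrong-species contamination in the pure samples.

    An amplicon is impure when the wrong species exceeds ``max_impurity``
    (strictly more than 5% by default) of its reads in either pure sample.
    Missing pure samples leave the flag undetermined.
    """
    amps = sorted(counts["amplicon_id"].unique())
    out = pd.DataFrame({"amplicon_id": amps}).set_index("amplicon_id")
    for sample, wrong_col, col in (
        (pure_target_sample, "n_competitor", "impurity_in_pure_target"),
        (pure_competitor_sample, "n_target", "impurity_in_pure_competitor"),
    ):
        block = counts[counts["sample_id"] == sample]
        if block.empty:
            logger.warning("pure sample %s missing; purity undetermined", sample)
            out[col] = float("nan")
            continue
        block = block.set_index("amplicon_id")
        depth = block["n_target"] + block["n_competitor"]
        out[col] = (block[wrong_col] / depth.where(depth > 0)).reindex(out.index)
    imp = out[["impurity_in_pure_target", "impurity_in_pure_competitor"]]
    if imp.isna().all().all():
        out["impure"] = pd.array([pd.NA] * len(out), dtype="boolean")
    else:
        out["impure"] = (imp > max_impurity).any(axis=1)
    return out.reset_index()
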