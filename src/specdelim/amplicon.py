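"""Bespoke amplicon read-to-genotype calling for pooled, MID-tagged loci.

Pyrosequencing amplicon data carry two systematic artifacts: single-base
insertions/deletions at homopolymer runs, and chimeric reads formed from
two parent alleles with one crossover breakpoint.  The protocol here is a
conservative filter chain for diploid allele calling under those error
modes:

1. demultiplex by exact MID tag-pair match and strip target primers
   (forward primer at the 5' end, reverse complement of the reverse
   primer at the 3' end; anything else is discarded with a reason code);
2. collapse perfectly identical reads per individual, keeping copy counts;
3. drop variants below a coverage threshold (default 10x);
4. drop sequences whose indel, in a locus-wide alignment, is carried by
   exactly one distinct sequence in the whole locus (homopolymer signature);
5. drop per-individual variants that are exact single-breakpoint
   recombinants of that individual's two highest-coverage variants;
6. call the two highest-coverage surviving sequences as the alleles.

Every removal is logged with the rule that fired, so the audit trail
accounts for every input read.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .syndata import reverse_complement

__all__ = [
    "Read",
    "VariantRecord",
    "GenotypeCall",
    "demultiplex_and_trim",
    "collapse_duplicates",
    "filter_variants",
    "call_genotype",
    "genotype_pipeline",
]


class DataError(ValueError):
    """Malformed input data (empty or unalignable sequences, etc.)."""


class AmpliconConfigurationError(ValueError):
    """Invalid run configuration (duplicate tag pairs, empty primers)."""


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"read {self.id}: empty sequence")


@dataclass
class VariantRecord:
    """A unique insert sequence of one individual at one locus."""

    sequence: str
    copy_count: int
    individual_id: str
    locus_id: str


@dataclass
class GenotypeCall:
    individual_id: str
    locus_id: str
    alleles: tuple[str, ...]  # 0, 1 or 2 sequences
    allele_coverages: tuple[int, ...]
    status: str  # heterozygote | homozygote | no_call
    audit: list[tuple[VariantRecord, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex_and_trim(
    reads: Iterable[Read],
    mid_table: Mapping[str, tuple[str, str]],
    primer_pair: tuple[str, str],
    min_length: int | None = None,
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Assign reads to individuals by exact MID-pair match and strip tags
    and primers.

    ``mid_table`` maps individual -> (forward MID, reverse MID), both given
    in the orientation of the forward strand of the amplicon; on the read
    the reverse MID appears reverse-complemented at the 3' end.  A read is
    kept iff it is at least ``min_length`` long, both tags of exactly one
    individual match, the forward primer follows the forward tag, and the
    reverse complement of the reverse primer precedes the 3' tag.  Returns
    ``(inserts_by_individual, discards)`` where discards are
    ``(read_id, reason)`` with reasons ``too_short``, ``mid_mismatch`` or
    ``primer_missing``.

    ``min_length`` defaults to combined tag+primer length + 50.
    """
    fwd_primer, rev_primer = primer_pair
    if not fwd_primer or not rev_primer:
        raise AmpliconConfigurationError("primers must be non-empty")
    pairs = list(mid_table.values())
    if len(set(pairs)) != len(pairs):
        dupes = [p for p, c in Counter(pairs).items() if c > 1]
        raise AmpliconConfigurationError(f"duplicate MID tag pair(s): {dupes}")
    tag_lengths = {(len(f), len(r)) for f, r in pairs}
    lookup = {
        (f, reverse_complement(r)): ind for ind, (f, r) in mid_table.items()
    }
    rev_primer_rc = reverse_complement(rev_primer)
    if min_length is None:
        max_f = max(len(f) for f, _ in pairs)
        max_r = max(len(r) for _, r in pairs)
        min_length = max_f + max_r + len(fwd_primer) + len(rev_primer) + 50

    inserts: dict[str, list[str]] = defaultdict(list)
    discards: list[tuple[str, str]] = []
    for read in reads:
        seq = read.sequence
        if len(seq) < min_length:
            discards.append((read.id, "too_short"))
            continue
        individual = None
        for flen, rlen in tag_lengths:
            key = (seq[:flen], seq[len(seq) - rlen :])
            if key in lookup:
                individual = lookup[key]
                detagged = seq[flen : len(seq) - rlen]
                break
        if individual is None:
            discards.append((read.id, "mid_mismatch"))
            continue
        if not (
            detagged.startswith(fwd_primer)
            and detagged.endswith(rev_primer_rc)
            and len(detagged) > len(fwd_primer) + len(rev_primer_rc)
        ):
            discards.append((read.id, "primer_missing"))
            continue
        insert = detagged[len(fwd_primer) : len(detagged) - len(rev_primer_rc)]
        inserts[individual].append(insert)
    return dict(inserts), discards


def collapse_duplicates(
    inserts_by_individual: Mapping[str, Sequence[str]], locus_id: str
) -> list[VariantRecord]:
    """One record per distinct insert per individual, with copy counts.

    The sum of copy counts equals the number of input inserts.  Records
    are ordered by individual, then descending copy count, then sequence.
    """
    records: list[VariantRecord] = []
    for individual in sorted(inserts_by_individual):
        counts = Counter(inserts_by_individual[individual])
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            records.append(
                VariantRecord(
                    sequence=seq,
                    copy_count=n,
                    individual_id=individual,
                    locus_id=locus_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# locus-wide alignment for the singleton-indel rule


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _indel_events(
    seq: str, reference: str, aligner: Align.PairwiseAligner
) -> frozenset[tuple]:
    """Indel events of ``seq`` relative to ``reference``.

    Events are keyed by reference coordinate: a deletion of reference
    slice [a, b) is ``("del", a, b)``; an insertion of ``s`` at reference
    position a is ``("ins", a, s)``.  Two distinct sequences share an
    event iff the same key appears for both — a reference-anchored stand-in
    for a shared indel column in a full multiple alignment.
    """
    if not seq or not reference:
        raise DataError("cannot align empty sequence")
    alignment = aligner.align(reference, seq)[0]
    ref_blocks, query_blocks = alignment.aligned
    events: set[tuple] = set()
    # gaps between consecutive aligned blocks
    prev_r_end, prev_q_end = 0, 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        if r0 > prev_r_end:
            events.add(("del", int(prev_r_end), int(r0)))
        if q0 > prev_q_end:
            events.add(("ins", int(r0), seq[prev_q_end:q0]))
        prev_r_end, prev_q_end = r1, q1
    if prev_r_end < len(reference):
        events.add(("del", int(prev_r_end), len(reference)))
    if prev_q_end < len(seq):
        events.add(("ins", len(reference), seq[prev_q_end:]))
    return frozenset(events)


def _singleton_indel_sequences(
    sequences: Sequence[str], aligner: Align.PairwiseAligner
) -> set[str]:
    """Distinct sequences carrying an indel event unique in the locus.

    The reference is the most frequent distinct sequence passed first in
    ``sequences`` (callers sort by total coverage).  Iterates removal to a
    fixed point: discarding one sequence can orphan an indel that another
    sequence shared, which then becomes a singleton itself.
    """
    reference = sequences[0]
    events = {s: _indel_events(s, reference, aligner) for s in sequences}
    removed: set[str] = set()
    while True:
        support: Counter = Counter()
        for s, evs in events.items():
            if s in removed:
                continue
            support.update(evs)
        newly = {
            s
            for s, evs in events.items()
            if s not in removed and any(support[e] == 1 for e in evs)
        }
        if not newly:
            return removed
        removed |= newly


def _is_chimera_of(
    seq: str, parent_a: str, parent_b: str, max_mismatch: int = 0
) -> bool:
    """True iff ``seq`` equals prefix(parent_a)+suffix(parent_b) or the
    reverse, for some single breakpoint, within ``max_mismatch`` substitutions."""
    for p1, p2 in ((parent_a, parent_b), (parent_b, parent_a)):
        if len(seq) != len(p2):
            continue
        limit = min(len(p1), len(p2))
        for b in range(1, limit):
            candidate = p1[:b] + p2[b:]
            if candidate == seq:
                return True
            if max_mismatch and len(candidate) == len(seq):
                mism = sum(1 for x, y in zip(candidate, seq) if x != y)
                if mism <= max_mismatch:
                    return True
    return False


def filter_variants(
    variants: Sequence[VariantRecord],
    coverage_threshold: int = 10,
    chimera_max_mismatch: int = 0,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the three filter rules to all variants of one locus.

    In order: (1) variants under ``coverage_threshold`` copies are removed
    (``low_coverage``); (2) sequences whose indel, relative to the
    locus-wide alignment, occurs in exactly one distinct sequence of the
    locus are removed (``singleton_indel``); (3) per individual, variants
    that are exact single-breakpoint recombinants of the individual's two
    highest-coverage surviving variants are removed (``chimera``).  Returns
    ``(retained, audit)``; the audit lists every removed variant with its
    rule.  The chain is idempotent: running it on its own output removes
    nothing further.
    """
    if aligner is None:
        aligner = _make_aligner()

    audit: list[tuple[VariantRecord, str]] = []
    survivors = []
    for v in variants:
        if v.copy_count < coverage_threshold:
            audit.append((v, "low_coverage"))
        else:
            survivors.append(v)

    if survivors:
        for v in survivors:
            if not v.sequence:
                raise DataError(
                    f"{v.individual_id}: empty variant sequence cannot be aligned"
                )
        totals: Counter = Counter()
        for v in survivors:
            totals[v.sequence] += v.copy_count
        distinct = sorted(totals, key=lambda s: (-totals[s], s))
        if len(distinct) > 1:
            bad = _singleton_indel_sequences(distinct, aligner)
            still = []
            for v in survivors:
                if v.sequence in bad:
                    audit.append((v, "singleton_indel"))
                else:
                    still.append(v)
            survivors = still

    retained: list[VariantRecord] = []
    by_individual: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in survivors:
        by_individual[v.individual_id].append(v)
    for individual in sorted(by_individual):
        ranked = sorted(
            by_individual[individual], key=lambda v: (-v.copy_count, v.sequence)
        )
        if len(ranked) <= 2:
            retained.extend(ranked)
            continue
        top1, top2 = ranked[0], ranked[1]
        retained.extend([top1, top2])
        for v in ranked[2:]:
            if _is_chimera_of(
                v.sequence, top1.sequence, top2.sequence, chimera_max_mismatch
            ):
                audit.append((v, "chimera"))
            else:
                retained.append(v)
    return retained, audit


def call_genotype(
    variants: Sequence[VariantRecord],
    filter_audit: Sequence[tuple[VariantRecord, str]] = (),
) -> GenotypeCall:
    """Call up to two alleles from one individual's filtered variants.

    Two or more surviving variants: heterozygote with the two
    highest-coverage sequences (ties between ranks 2 and 3 are broken
    lexicographically and flagged in the audit); exactly one: homozygote;
    none: no call.
    """
    if not variants:
        ids = {(v.individual_id, v.locus_id) for v, _ in filter_audit}
        ind, locus = ids.pop() if len(ids) == 1 else ("", "")
        return GenotypeCall(ind, locus, (), (), "no_call", list(filter_audit))
    individual = variants[0].individual_id
    locus = variants[0].locus_id
    if any(v.individual_id != individual for v in variants):
        raise DataError("call_genotype expects variants of a single individual")
    audit = list(filter_audit)
    ranked = sorted(variants, key=lambda v: (-v.copy_count, v.sequence))
    if len(ranked) == 1:
        v = ranked[0]
        return GenotypeCall(
            individual, locus, (v.sequence,), (v.copy_count,), "homozygote", audit
        )
    if len(ranked) > 2 and ranked[1].copy_count == ranked[2].copy_count:
        audit.append((ranked[2], "rank2_rank3_coverage_tie"))
    a, b = ranked[0], ranked[1]
    return GenotypeCall(
        individual,
        locus,
        (a.sequence, b.sequence),
        (a.copy_count, b.copy_count),
        "heterozygote",
        audit,
    )


def genotype_pipeline(
    reads: Iterable[Read],
    mid_table: Mapping[str, tuple[str, str]],
    primer_pair: tuple[str, str],
    locus_id: str,
    coverage_threshold: int = 10,
    min_length: int | None = None,
    chimera_max_mismatch: int = 0,
    apply_filters: bool = True,
) -> tuple[dict[str, GenotypeCall], list[tuple[str, str]]]:
    """Demultiplex -> collapse -> filter -> call, for one locus.

    Returns ``(calls_by_individual, read_discards)``.  ``apply_filters``
    exists so filter benefit can be measured against a naive top-2 call.
    """
    inserts, discards = demultiplex_and_trim(reads, mid_table, primer_pair, min_length)
    variants = collapse_duplicates(inserts, locus_id)
    if apply_filters:
        retained, audit = filter_variants(
            variants, coverage_threshold, chimera_max_mismatch
        )
    else:
        retained, audit = list(variants), []
    by_individual: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in retained:
        by_individual[v.individual_id].append(v)
    audit_by_individual: dict[str, list] = defaultdict(list)
    for v, rule in audit:
        audit_by_individual[v.individual_id].append((v, rule))
    calls = {}
    for individual in sorted(set(by_individual) | set(audit_by_individual)):
        call = call_genotype(
            by_individual.get(individual, []), audit_by_individual.get(individual, [])
        )
        call.individual_id = call.individual_id or individual
        call.locus_id = call.locus_id or locus_id
        calls[individual] = call
    return calls, discards


def genotype_table(calls: Mapping[str, GenotypeCall]):
    """Calls as a tidy frame: individual, locus, alleles, coverages, status."""
    import pandas as pd

    rows = []
    for ind, call in sorted(calls.items()):
        alleles = list(call.alleles) + [""] * (2 - len(call.alleles))
        covs = list(call.allele_coverages) + [0] * (2 - len(call.allele_coverages))
        rows.append(
            {
                "individual": ind,
                "locus": call.locus_id,
                "allele_1": alleles[0],
                "allele_2": alleles[1],
                "coverage_1": covs[0],
                "coverage_2": covs[1],
                "status": call.status,
            }
        )
    return pd.DataFrame(rows)
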