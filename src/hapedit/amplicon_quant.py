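"""Amplicon-sequencing readouts of allele-specific editing.

Three analyses over merged single-end reads:

* **Allele deconvolution** — assign each read to one of the two alleles of
  a heterozygous SNP carried by the amplicon, via the base aligned to the
  SNP position (reads with a gap or foreign base there, or with poor
  overall identity, stay unassigned).
* **Indel quantification** — a read counts as edited iff its alignment to
  the reference contains an insertion or deletion overlapping a small
  window around the nuclease cut site (substitutions never count); the
  result is an edited fraction and a net-indel-size spectrum, typically
  computed per allele after deconvolution.
* **Excision-junction classification** — reads spanning the repair
  junction of a two-cut excision are matched against a candidate library:
  the precise junction, microhomology-collapse junctions (exact repeats
  flanking the two cuts, producing characteristically larger deletions),
  and small (<= 3 nt) insertions/deletions at the junction; anything else
  is aligned to the expected junction and reported as other_imprecise.

Alignment uses affine-gap scoring (match +2, mismatch -1, gap open -6,
extend -1) with free end gaps at the read ends, so that contiguous indels
are preferred over runs of scattered mismatches; read orientation is
auto-detected by best-strand score.  Equal-length reads with high identity
take a hamming-distance fast path, which is exact under a
substitution-only error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import reverse_complement

from .synthetic_data import parse_outcome


class AmpliconError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with its discriminating SNP and cut site(s).

    ``cut_positions`` are 0-based inter-base coordinates (for SpCas9, the
    blunt cut 3 nt 5' of the PAM, i.e. between protospacer positions 17
    and 18).
    """

    sequence: str
    snp_offset: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    cut_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.snp_offset is not None:
            if not 0 <= self.snp_offset < len(self.sequence):
                raise AmpliconError("snp_offset outside amplicon")
            if self.ref_base == self.alt_base:
                raise AmpliconError("SNP alleles must differ")
        for c in self.cut_positions:
            if not 0 < c < len(self.sequence):
                raise AmpliconError(f"cut position {c} not strictly inside amplicon")


@dataclass(frozen=True)
class Microhomology:
    """An exact repeat whose collapse mimics a larger-than-precise excision.

    One copy ends ``left_offset`` bases 5' of the left cut, the other
    starts ``right_offset`` bases 3' of the right cut; annealing the
    copies deletes ``extra_deletion = left_offset + right_offset + length``
    nt relative to the precise junction.
    """

    length: int
    left_offset: int
    right_offset: int

    @property
    def extra_deletion(self) -> int:
        return self.left_offset + self.right_offset + self.length


def annotate_microhomology(
    left_context: str,
    right_context: str,
    max_len: int = 10,
    min_len: int = 2,
    max_offset: int = 4,
) -> list[Microhomology]:
    """All exact repeats around the two cuts that could template MMEJ.

    ``left_context`` ends at the left cut; ``right_context`` starts at the
    right cut.  Returns annotations sorted by extra deletion size, then
    descending repeat length.
    """
    found = []
    for k in range(min_len, max_len + 1):
        for a in range(0, max_offset + 1):
            if a + k > len(left_context):
                break
            left_copy = left_context[len(left_context) - a - k: len(left_context) - a]
            for b in range(0, max_offset + 1):
                if b + k > len(right_context):
                    break
                if left_copy == right_context[b: b + k]:
                    found.append(Microhomology(k, a, b))
    return sorted(found, key=lambda m: (m.extra_deletion, -m.length, m.left_offset))


@dataclass
class JunctionModel:
    """Expected excision repair junction plus its microhomology annotations."""

    left_flank: str
    right_flank: str
    microhomologies: list[Microhomology] = field(default_factory=list)

    @property
    def expected_junction(self) -> str:
        return self.left_flank + self.right_flank

    @classmethod
    def from_flanks(
        cls, left_flank: str, right_flank: str, max_mh_len: int = 10, max_mh_offset: int = 4
    ) -> "JunctionModel":
        return cls(
            left_flank,
            right_flank,
            annotate_microhomology(
                left_flank, right_flank, max_len=max_mh_len, max_offset=max_mh_offset
            ),
        )

    def mh_junction(self, mh: Microhomology) -> str:
        """The repair product of collapsing one microhomology."""
        a = mh.left_offset
        left = self.left_flank[:-a] if a else self.left_flank
        return left + self.right_flank[mh.right_offset + mh.length:]


# ---------------------------------------------------------------------------
# alignment machinery


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    # affine: a gap of length L costs 6 + L
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = make_aligner()


def _best_strand(read: str, reference: str) -> tuple[str, object]:
    """Align the read on both strands; return (oriented read, alignment)."""
    fwd = _ALIGNER.align(reference, read)
    rc = reverse_complement(read)
    rev = _ALIGNER.align(reference, rc)
    if rev.score > fwd.score:
        return rc, rev[0]
    return read, fwd[0]


@dataclass
class _AlignedRead:
    read: str
    matches: int
    mismatches: int
    indels: list  # (kind, target_pos, length, seq); deletions span [pos, pos+len)
    aligned_read_bases: int

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches
        return self.matches / denom if denom else 0.0


def _analyze_alignment(aln, reference: str, read: str) -> _AlignedRead:
    t_blocks, q_blocks = aln.aligned
    matches = mismatches = aligned = 0
    indels = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            if dt > 0:
                indels.append(("del", prev_t, dt, reference[prev_t:ts]))
            if dq > 0:
                indels.append(("ins", prev_t, dq, read[prev_q:qs]))
        sub_t, sub_q = reference[ts:te], read[qs:qe]
        eq = sum(a == b for a, b in zip(sub_t, sub_q))
        matches += eq
        mismatches += (te - ts) - eq
        aligned += qe - qs
        prev_t, prev_q = te, qe
    return _AlignedRead(read, matches, mismatches, indels, aligned)


def _read_base_at(aln, read: str, target_pos: int) -> str | None:
    """Base of the read aligned to a reference position, or None in a gap."""
    t_blocks, q_blocks = aln.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts <= target_pos < te:
            return read[qs + (target_pos - ts)]
    return None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# allele deconvolution


@dataclass
class Deconvolution:
    """Read indices per allele bin (indices into the input read list)."""

    ref_indices: list
    alt_indices: list
    unassigned_indices: list

    def subset(self, reads: list, which: str) -> list:
        idx = getattr(self, f"{which}_indices")
        return [reads[i] for i in idx]


def deconvolute_by_allele(
    reads: list, ref: AmpliconReference, max_mismatch_rate: float = 0.1
) -> Deconvolution:
    """Assign reads to alleles by the base covering the heterozygous SNP.

    A read is unassigned when the SNP position is deleted, carries a base
    matching neither allele (or N), or the alignment identity falls below
    ``1 - max_mismatch_rate``.
    """
    if ref.snp_offset is None or ref.ref_base is None or ref.alt_base is None:
        raise AmpliconError("reference lacks a heterozygous SNP definition")
    reference = ref.sequence
    bins = Deconvolution([], [], [])
    for i, read in enumerate(reads):
        base = None
        if len(read) == len(reference):
            mm = _hamming(read, reference)
            # substitution-only fast path; high mismatch load falls through
            # to the aligner in case the length match hides offsetting indels
            if mm / len(read) <= max_mismatch_rate:
                base = read[ref.snp_offset]
        if base is None:
            oriented, aln = _best_strand(read, reference)
            stats = _analyze_alignment(aln, reference, oriented)
            if stats.identity < 1.0 - max_mismatch_rate:
                bins.unassigned_indices.append(i)
                continue
            base = _read_base_at(aln, oriented, ref.snp_offset)
        if base == ref.ref_base:
            bins.ref_indices.append(i)
        elif base == ref.alt_base:
            bins.alt_indices.append(i)
        else:
            bins.unassigned_indices.append(i)
    return bins


# ---------------------------------------------------------------------------
# indel quantification


@dataclass
class IndelQuant:
    n_reads: int
    n_edited: int
    spectrum: dict  # net indel size -> read count (edited reads only)

    @property
    def edited_fraction(self) -> float:
        return self.n_edited / self.n_reads if self.n_reads else 0.0


def _indel_placement_range(
    kind: str, pos: int, length: int, seq: str, reference: str, max_shift: int = 30
) -> tuple[int, int]:
    """Range of alignment-equivalent positions of one indel.

    An indel inside a repeat can be placed anywhere along it without
    changing the aligned sequence; the aligner reports one arbitrary
    placement.  Returns the inter-base interval ``[lo, hi]`` spanned by
    all equivalent placements (for deletions, including the deleted span).
    """
    if kind == "del":
        lo = pos
        while lo > 0 and pos - lo < max_shift \
                and reference[lo - 1] == reference[lo + length - 1]:
            lo -= 1
        hi = pos
        while hi + length < len(reference) and hi - pos < max_shift \
                and reference[hi] == reference[hi + length]:
            hi += 1
        return lo, hi + length
    # insertion: rotate the inserted sequence while it matches the flank
    lo = pos
    s = seq
    shifts = 0
    while lo > 0 and shifts < max_shift and reference[lo - 1] == s[-1]:
        s = s[-1] + s[:-1]
        lo -= 1
        shifts += 1
    hi = pos
    s = seq
    shifts = 0
    while hi < len(reference) and shifts < max_shift and reference[hi] == s[0]:
        s = s[1:] + s[0]
        hi += 1
        shifts += 1
    return lo, hi


def quantify_indels(
    reads: list,
    ref: AmpliconReference,
    cut_position: int | None = None,
    window_halfwidth: int = 1,
) -> IndelQuant:
    """Edited fraction and net-indel-size spectrum around one cut site.

    A read is edited iff its alignment contains an insertion or deletion
    whose (alignment-equivalence) placement range overlaps the inter-base
    window ``[cut - w, cut + w]``; pure substitutions never count.
    """
    if cut_position is None:
        if not ref.cut_positions:
            raise AmpliconError("no cut position designated")
        cut_position = ref.cut_positions[0]
    lo, hi = cut_position - window_halfwidth, cut_position + window_halfwidth
    reference = ref.sequence
    n_edited = 0
    spectrum: dict[int, int] = {}
    for read in reads:
        if len(read) == len(reference) and _hamming(read, reference) / len(reference) <= 0.1:
            continue  # substitution-only read: no indel anywhere
        oriented, aln = _best_strand(read, reference)
        stats = _analyze_alignment(aln, reference, oriented)
        net = 0
        hit = False
        for kind, pos, length, seq in stats.indels:
            r_lo, r_hi = _indel_placement_range(kind, pos, length, seq, reference)
            if r_lo <= hi and r_hi >= lo:
                hit = True
                net += length if kind == "ins" else -length
        if hit:
            n_edited += 1
            spectrum[net] = spectrum.get(net, 0) + 1
    return IndelQuant(len(reads), n_edited, spectrum)


def allele_edit_rates(
    reads: list,
    ref: AmpliconReference,
    cut_position: int | None = None,
    window_halfwidth: int = 1,
    max_mismatch_rate: float = 0.1,
) -> dict:
    """Deconvolute by allele, then quantify indels per allele bin."""
    bins = deconvolute_by_allele(reads, ref, max_mismatch_rate)
    out = {}
    for which, base in (("ref", ref.ref_base), ("alt", ref.alt_base)):
        subset = bins.subset(reads, which)
        out[base] = quantify_indels(subset, ref, cut_position, window_halfwidth)
    out["n_unassigned"] = len(bins.unassigned_indices)
    return out


# ---------------------------------------------------------------------------
# junction classification


@dataclass
class JunctionCall:
    """Per-read junction classes and their aggregate fractions."""

    labels: list  # per read: "precise", "mh_del(k)", "ins(k)", "del(k)",
    #               "other_imprecise(net)", or "unassigned"
    class_counts: dict
    n_assigned: int

    @property
    def fractions(self) -> dict:
        """Fractions over assigned reads (sum to 1)."""
        if not self.n_assigned:
            return {}
        return {k: v / self.n_assigned for k, v in sorted(self.class_counts.items())}

    @property
    def imprecise_fraction(self) -> float:
        """Pooled fraction of assigned reads that are not the precise junction."""
        if not self.n_assigned:
            return 0.0
        return 1.0 - self.class_counts.get("precise", 0) / self.n_assigned


def _simplify_label(label: str) -> str:
    return label.split("(")[0] if label.startswith("other_imprecise") else label


def classify_junction_reads(
    reads: list,
    model: JunctionModel,
    tolerance: int = 0,
    max_small_indel: int = 3,
    min_read_length: int = 30,
    max_mismatch_rate: float = 0.1,
) -> JunctionCall:
    """Classify excision-junction reads by candidate-library matching.

    Each read is compared (allowing up to ``tolerance`` substitutions)
    against the precise junction, every microhomology-collapse junction of
    the model, and all ±k small-indel junctions for k <= ``max_small_indel``
    (candidates are tried in that order, so a deletion explainable by a
    >= 2 nt repeat is called mh_del, while 1-nt repeats fall through to the
    plain small-indel class).  Reads over the cap but still closest to one
    candidate at <= ``max_mismatch_rate`` take that candidate's class, so
    ordinary sequencing errors do not leak reads out of their class;
    remaining reads are aligned to the expected junction and reported as
    ``other_imprecise`` with their net indel size.
    """
    left, right = model.left_flank, model.right_flank
    precise = model.expected_junction

    # exact-sequence candidates, in priority order
    candidates: list[tuple[str, str]] = [(precise, "precise")]
    seen = {precise}
    for mh in model.microhomologies:
        junc = model.mh_junction(mh)
        if junc not in seen:
            candidates.append((junc, f"mh_del({mh.extra_deletion})"))
            seen.add(junc)
    for k in range(1, max_small_indel + 1):
        for a in range(0, k + 1):
            b = k - a
            junc = (left[:-a] if a else left) + right[b:]
            if junc not in seen:
                candidates.append((junc, f"del({k})"))
                seen.add(junc)

    by_len: dict[int, list[tuple[np.ndarray, str]]] = {}
    for seq, label in candidates:
        by_len.setdefault(len(seq), []).append(
            (np.frombuffer(seq.encode(), dtype=np.uint8), label)
        )
    left_arr = np.frombuffer(left.encode(), dtype=np.uint8)
    right_arr = np.frombuffer(right.encode(), dtype=np.uint8)
    n_precise = len(precise)

    ref_amp = AmpliconReference(precise, cut_positions=(len(left),))
    labels: list[str] = []
    for read in reads:
        if len(read) < min_read_length:
            labels.append("unassigned")
            continue
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        label = None
        best_mm = len(read) + 1
        best_label = None
        for cand, cand_label in by_len.get(len(read), ()):
            mm = int(np.count_nonzero(arr != cand))
            if mm <= tolerance:
                label = cand_label
                break
            if mm < best_mm:
                best_mm, best_label = mm, cand_label
        if label is None and n_precise < len(read) <= n_precise + max_small_indel:
            # insertion at the junction: flanks match around an arbitrary insert
            k = len(read) - n_precise
            mm = int(np.count_nonzero(arr[: len(left)] != left_arr)) + int(
                np.count_nonzero(arr[len(left) + k:] != right_arr)
            )
            if mm <= tolerance:
                label = f"ins({k})"
            elif mm < best_mm:
                best_mm, best_label = mm, f"ins({len(read) - n_precise})"
        if label is None and best_label is not None \
                and best_mm <= max_mismatch_rate * len(read):
            label = best_label
        if label is None:
            _, aln = _best_strand(read, precise)
            stats = _analyze_alignment(aln, precise, read)
            net = sum(
                length if kind == "ins" else -length
                for kind, _, length, _seq in stats.indels
            )
            net += len(read) - stats.aligned_read_bases  # unaligned read ends
            label = f"other_imprecise({net:+d})" if stats.identity >= 0.5 else "unassigned"
        labels.append(label)

    class_counts: dict[str, int] = {}
    n_assigned = 0
    for lab in labels:
        if lab == "unassigned":
            continue
        key = _simplify_label(lab)
        class_counts[key] = class_counts.get(key, 0) + 1
        n_assigned += 1
    return JunctionCall(labels, class_counts, n_assigned)


def mixture_from_call(call: JunctionCall) -> dict:
    """Aggregate class fractions keyed like the simulator's outcome keys."""
    return call.fractions


def expected_label(outcome_key: str) -> str:
    """Map a simulator outcome key to the classifier label it should get."""
    kind, size = parse_outcome(outcome_key)
    if kind == "precise":
        return "precise"
    if kind == "mh_del":
        return f"mh_del({size})"
    if kind == "ins":
        return f"ins({size})"
    return f"del({size})"
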