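"""Seeded generators for panels, digital-PCR partitions, and amplicon reads.

Every generator is a pure function of its parameters and an integer seed,
and returns a :class:`TruthRecord` alongside the dataset so downstream
estimators can be tested for parameter recovery.  The statistical structure
emulated:

* **Panels** — 2n haplotypes drawn i.i.d. from an explicit haplotype
  frequency distribution over a small number of flanking SNPs, the regime
  in which double-heterozygote counting and greedy therapy selection
  operate.
* **Partitions** — multinomial loading: each template molecule picks one of
  ``n_partitions`` chambers uniformly, so per-chamber occupancy is
  asymptotically Poisson (the assumption behind digital-PCR λ estimation)
  while molecule counts are conserved exactly.  A chamber is positive in a
  fluorophore channel iff at least one resident molecule carries that
  channel, which makes co-occurrence of channels on one molecule (e.g. an
  excision junction physically linked to a haplotype SNP) emerge without
  any explicit linkage parameter.
* **Amplicon reads** — merged single reads over an edited locus, with
  substitution-only sequencing error and constant quality (Q40); junction
  reads realise a programmed mixture of precise, microhomology-deletion
  and small-indel repair outcomes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import GenomicInterval, PhasedPanel, SNPSite

CHANNELS = ("FAM", "HEX", "VIC", "ROX", "CY5")
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


class GeneratorError(ValueError):
    """Invalid generator parameters."""


@dataclass
class TruthRecord:
    """Sidecar holding everything needed to regenerate and check a dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"generator": self.generator, "seed": self.seed, "params": self.params},
                fh, indent=2, sort_keys=True, default=_jsonify,
            )

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["generator"], d["seed"], d["params"])


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass(frozen=True)
class MoleculeSpecies:
    """A template species: which channels it lights up, and how many copies."""

    name: str
    channels: frozenset
    copies: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", frozenset(self.channels))
        if not self.channels:
            raise GeneratorError(f"species {self.name!r}: empty channel signature")
        unknown = self.channels - set(CHANNELS)
        if unknown:
            raise GeneratorError(f"species {self.name!r}: unknown channels {sorted(unknown)}")
        if self.copies < 0:
            raise GeneratorError(f"species {self.name!r}: negative copy number")


_OUTCOME_RE = re.compile(r"^(precise|mh_del|ins|del)(?:\((\d+)\))?$")


def parse_outcome(key: str) -> tuple[str, int]:
    """Parse an outcome key like ``"precise"``, ``"mh_del(5)"``, ``"ins(1)"``."""
    m = _OUTCOME_RE.match(key)
    if not m:
        raise GeneratorError(f"unparseable outcome key {key!r}")
    kind, size = m.group(1), m.group(2)
    if kind == "precise":
        if size is not None:
            raise GeneratorError("'precise' takes no size")
        return kind, 0
    if size is None or int(size) < 1:
        raise GeneratorError(f"outcome {key!r} needs a positive size")
    return kind, int(size)


@dataclass(frozen=True)
class OutcomeMixture:
    """Proportions over repair-junction outcome classes (must sum to 1)."""

    proportions: dict  # outcome key -> fraction

    def __post_init__(self) -> None:
        for k in self.proportions:
            parse_outcome(k)
        if any(p < 0 for p in self.proportions.values()):
            raise GeneratorError("mixture proportions must be nonnegative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorError(f"mixture proportions sum to {total}, not 1")

    def items(self) -> list[tuple[str, float]]:
        return sorted(self.proportions.items())


# ---------------------------------------------------------------------------
# panel generator


def simulate_panel(
    n_individuals: int,
    haplotype_freqs: dict,
    seed: int,
    sites: list[SNPSite] | None = None,
    chrom: str = "chr8",
    positions: list[int] | None = None,
) -> tuple[PhasedPanel, TruthRecord]:
    """Draw ``2 * n_individuals`` haplotypes i.i.d. from a haplotype
    distribution given as ``{'010...': freq, ...}`` over an implicit site list.

    If ``sites`` is omitted, placeholder A/G SNPs are created (at
    ``positions`` if given, else spaced 1 kb apart).  Site alt-frequencies
    are recomputed from the realised matrix.
    """
    if n_individuals <= 0:
        raise GeneratorError("n_individuals must be positive")
    haps = sorted(haplotype_freqs)
    if not haps:
        raise GeneratorError("haplotype distribution is empty")
    lengths = {len(h) for h in haps}
    if len(lengths) != 1:
        raise GeneratorError("haplotype strings must all have the same length")
    n_sites = lengths.pop()
    if n_sites == 0:
        raise GeneratorError("site list is empty")
    freqs = np.array([haplotype_freqs[h] for h in haps], dtype=float)
    if (freqs < 0).any():
        raise GeneratorError("haplotype frequencies must be nonnegative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise GeneratorError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
    if any(set(h) - {"0", "1"} for h in haps):
        raise GeneratorError("haplotype strings must be over {0,1}")

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(haps), size=2 * n_individuals, p=freqs)
    hap_matrix = np.array([[int(c) for c in h] for h in haps], dtype=np.int8)
    matrix = hap_matrix[draws]

    if sites is None:
        if positions is None:
            positions = [1000 * (i + 1) for i in range(n_sites)]
        if len(positions) != n_sites:
            raise GeneratorError("positions length must match haplotype length")
        sites = [
            SNPSite(f"snp{i + 1}", chrom, int(p), "A", "G", 0.0)
            for i, p in enumerate(positions)
        ]
    elif len(sites) != n_sites:
        raise GeneratorError("sites length must match haplotype length")

    panel = PhasedPanel(list(sites), [f"ind{k + 1}" for k in range(n_individuals)], matrix)
    panel = panel.with_recomputed_frequencies()
    truth = TruthRecord(
        "simulate_panel", seed,
        {"n_individuals": n_individuals, "haplotype_freqs": dict(haplotype_freqs)},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# digital-PCR partition generator


def simulate_partitions(
    n_partitions: int,
    species: list[MoleculeSpecies],
    seed: int,
    false_pos_rate: float = 0.0,
    false_neg_rate: float = 0.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Load molecules into partitions and return the boolean positivity table.

    Columns: ``partition_id`` plus one 0/1 column per channel that appears
    in any species signature (canonical fluorophore order).  Error rates
    flip each channel call independently per partition.
    """
    if n_partitions <= 0:
        raise GeneratorError("n_partitions must be positive")
    for rate in (false_pos_rate, false_neg_rate):
        if not 0.0 <= rate <= 1.0:
            raise GeneratorError(f"error rate {rate} outside [0, 1]")
    channels = [c for c in CHANNELS if any(c in sp.channels for sp in species)]
    rng = np.random.default_rng(seed)
    positive = {c: np.zeros(n_partitions, dtype=bool) for c in channels}
    for sp in species:
        if sp.copies == 0:
            continue
        assignment = rng.integers(0, n_partitions, size=sp.copies)
        occupied = np.bincount(assignment, minlength=n_partitions) > 0
        for c in sp.channels:
            positive[c] |= occupied
    for c in channels:
        if false_neg_rate > 0:
            drop = rng.random(n_partitions) < false_neg_rate
            positive[c] &= ~drop
        if false_pos_rate > 0:
            add = rng.random(n_partitions) < false_pos_rate
            positive[c] |= add
    table = pd.DataFrame({"partition_id": np.arange(n_partitions)})
    for c in channels:
        table[c] = positive[c].astype(np.int8)
    truth = TruthRecord(
        "simulate_partitions", seed,
        {
            "n_partitions": n_partitions,
            "species": [
                {"name": sp.name, "channels": sorted(sp.channels), "copies": sp.copies}
                for sp in species
            ],
            "false_pos_rate": false_pos_rate,
            "false_neg_rate": false_neg_rate,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# read generators


def _apply_substitution_errors(reads: list[str], per_base_error: float, rng) -> list[str]:
    if per_base_error == 0:
        return reads
    out = []
    for seq in reads:
        n = len(seq)
        n_err = rng.binomial(n, per_base_error)
        if n_err == 0:
            out.append(seq)
            continue
        pos = rng.choice(n, size=n_err, replace=False)
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
        # substitute with one of the three *other* bases, uniformly
        for p in pos:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(3)]
        out.append("".join(arr))
    return out


def embed_microhomology(left_flank: str, right_flank: str, length: int) -> tuple[str, str]:
    """Rewrite ``right_flank`` so its first ``length`` bases repeat the last
    ``length`` bases of ``left_flank`` (the flush-repeat MMEJ substrate)."""
    if length < 1 or length > min(len(left_flank), len(right_flank)):
        raise GeneratorError(f"microhomology length {length} incompatible with flanks")
    return left_flank, left_flank[-length:] + right_flank[length:]


def junction_read(left_flank: str, right_flank: str, outcome: str, rng=None) -> str:
    """The error-free read sequence for one repair outcome."""
    kind, size = parse_outcome(outcome)
    if kind == "precise":
        return left_flank + right_flank
    if kind == "mh_del":
        if left_flank[-size:] != right_flank[:size]:
            raise GeneratorError(
                f"mh_del({size}) requires the last {size} nt of the left flank to "
                f"repeat at the start of the right flank; use embed_microhomology()"
            )
        return left_flank + right_flank[size:]
    if kind == "ins":
        if rng is None:
            rng = np.random.default_rng(0)
        insert = "".join(_BASE_ARR[rng.integers(4, size=size)])
        return left_flank + insert + right_flank
    # plain deletion spanning the junction, split between the two flanks
    a = size // 2
    b = size - a
    if a >= len(left_flank) or b >= len(right_flank):
        raise GeneratorError(f"del({size}) larger than flanks")
    return (left_flank[:-a] if a else left_flank) + right_flank[b:]


def simulate_junction_reads(
    left_flank: str,
    right_flank: str,
    mixture: OutcomeMixture,
    n_reads: int,
    per_base_error: float,
    seed: int,
) -> tuple[list[str], TruthRecord]:
    """Reads over an excision repair junction with a programmed outcome mixture.

    Per-read truth labels (outcome keys, aligned with the returned read
    list) are stored under ``params["labels"]``.
    """
    if len(left_flank) < 30 or len(right_flank) < 30:
        raise GeneratorError("flanks must be >= 30 nt")
    if not 0.0 <= per_base_error < 1.0:
        raise GeneratorError("per_base_error outside [0, 1)")
    rng = np.random.default_rng(seed)
    keys = [k for k, _ in mixture.items()]
    probs = np.array([p for _, p in mixture.items()])
    # validate mh requirements up front so errors do not depend on the draw
    for k in keys:
        kind, size = parse_outcome(k)
        if kind == "mh_del" and left_flank[-size:] != right_flank[:size]:
            raise GeneratorError(
                f"mixture class {k} incompatible with flanks; use embed_microhomology()"
            )
    assignments = rng.choice(len(keys), size=n_reads, p=probs) if n_reads else np.array([], int)
    labels = [keys[i] for i in assignments]
    reads = [junction_read(left_flank, right_flank, lab, rng) for lab in labels]
    reads = _apply_substitution_errors(reads, per_base_error, rng)
    truth = TruthRecord(
        "simulate_junction_reads", seed,
        {
            "left_flank": left_flank,
            "right_flank": right_flank,
            "mixture": dict(mixture.proportions),
            "n_reads": n_reads,
            "per_base_error": per_base_error,
            "labels": labels,
        },
    )
    return reads, truth


def simulate_allele_amplicon_reads(
    ref_amplicon: str,
    snp_offset: int,
    alleles: tuple[str, str],
    indel_rates: dict,
    n_reads: int,
    per_base_error: float,
    seed: int,
    cut_position: int | None = None,
    size_spectrum: dict | None = None,
    hap_ratio: float = 0.5,
) -> tuple[list[str], TruthRecord]:
    """Reads from a heterozygous amplicon with per-allele editing rates.

    ``indel_rates`` maps each allele base to its edit probability;
    ``size_spectrum`` maps signed indel sizes to proportions (default 50/50
    ±1 nt).  Indels are placed at ``cut_position`` (0-based inter-base
    coordinate).  Truth labels per read: ``{"allele", "edited", "size"}``.
    """
    if not 0 <= snp_offset < len(ref_amplicon):
        raise GeneratorError("snp_offset outside amplicon")
    a1, a2 = alleles
    if a1 == a2:
        raise GeneratorError("alleles must differ")
    if set(indel_rates) - {a1, a2}:
        raise GeneratorError("indel_rates keyed by allele base")
    if cut_position is None:
        cut_position = snp_offset + 10
    if not 0 < cut_position < len(ref_amplicon):
        raise GeneratorError(f"cut position {cut_position} outside amplicon")
    spectrum = size_spectrum or {1: 0.5, -1: 0.5}
    sizes = sorted(spectrum)
    size_p = np.array([spectrum[s] for s in sizes], dtype=float)
    if abs(size_p.sum() - 1.0) > 1e-9:
        raise GeneratorError("size spectrum must sum to 1")
    if 0 in sizes:
        raise GeneratorError("indel size 0 is not an edit")

    allele_seqs = {
        a: ref_amplicon[:snp_offset] + a + ref_amplicon[snp_offset + 1:] for a in (a1, a2)
    }
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    labels: list[dict] = []
    which = rng.random(n_reads) < hap_ratio
    for i in range(n_reads):
        allele = a1 if which[i] else a2
        seq = allele_seqs[allele]
        edited = bool(rng.random() < indel_rates.get(allele, 0.0))
        size = 0
        if edited:
            size = int(sizes[rng.choice(len(sizes), p=size_p)])
            if size > 0:
                insert = "".join(_BASE_ARR[rng.integers(4, size=size)])
                seq = seq[:cut_position] + insert + seq[cut_position:]
            else:
                if cut_position - size > len(seq):
                    raise GeneratorError(f"deletion of {-size} nt runs off amplicon")
                seq = seq[:cut_position] + seq[cut_position - size:]
        reads.append(seq)
        labels.append({"allele": allele, "edited": edited, "size": size})
    reads = _apply_substitution_errors(reads, per_base_error, rng)
    truth = TruthRecord(
        "simulate_allele_amplicon_reads", seed,
        {
            "ref_amplicon": ref_amplicon,
            "snp_offset": snp_offset,
            "alleles": [a1, a2],
            "indel_rates": {k: float(v) for k, v in indel_rates.items()},
            "cut_position": cut_position,
            "size_spectrum": {str(k): float(v) for k, v in spectrum.items()},
            "hap_ratio": hap_ratio,
            "n_reads": n_reads,
            "per_base_error": per_base_error,
            "labels": labels,
        },
    )
    return reads, truth


def multiplex_species(
    n_genomes: int, excision_fraction: float, target_specificity: float
) -> list[MoleculeSpecies]:
    """Molecule species of the 4-color excision/specificity assay.

    Each genome contributes one target allele (FAM-linked SNP), one
    non-target allele (VIC-linked) and two reference-locus copies (CY5);
    excised alleles additionally carry the junction probe (ROX) on the
    same molecule.
    """
    excised = round(excision_fraction * 2 * n_genomes)
    on_target = round(target_specificity * excised)
    off_target = excised - on_target
    return [
        MoleculeSpecies("excised_target", {"ROX", "FAM"}, on_target),
        MoleculeSpecies("excised_nontarget", {"ROX", "VIC"}, off_target),
        MoleculeSpecies("unedited_target", {"FAM"}, n_genomes - on_target),
        MoleculeSpecies("unedited_nontarget", {"VIC"}, n_genomes - off_target),
        MoleculeSpecies("reference_locus", {"CY5"}, 2 * n_genomes),
    ]


def simulate_multiplex_wells(
    n_partitions: int = 8500,
    wells: int = 3,
    genomes_per_well: int = 700,
    excision_fraction: float = 0.25,
    target_specificity: float = 0.92,
    seed: int = 0,
):
    """Simulate replicate wells of the 4-color assay and merge class counts.

    Returns ``(PartitionCounts, TruthRecord)``; the truth record carries
    the realised (integer-rounded) target specificity.
    """
    from .dpcr_quant import PartitionCounts, merge_wells

    species = multiplex_species(genomes_per_well, excision_fraction, target_specificity)
    rng = np.random.default_rng(seed)
    well_counts = []
    for _ in range(wells):
        table, _ = simulate_partitions(n_partitions, species, int(rng.integers(2**31)))
        well_counts.append(PartitionCounts.from_table(table))
    merged = merge_wells(well_counts)
    excised = round(excision_fraction * 2 * genomes_per_well)
    truth = TruthRecord(
        "simulate_multiplex_wells", seed,
        {
            "n_partitions": n_partitions, "wells": wells,
            "genomes_per_well": genomes_per_well,
            "excision_fraction": excision_fraction,
            "target_specificity": (round(target_specificity * excised) / excised
                                   if excised else 0.0),
        },
    )
    return merged, truth


def sample_aliquot(species: list[MoleculeSpecies], seed: int) -> list[MoleculeSpecies]:
    """Poisson-resample each species' copy number around its expectation.

    Models drawing an aliquot from bulk template DNA: the molecule count
    of each species in the analysed reaction is Poisson around its
    expected value.  Combined with multinomial loading this makes
    per-partition occupancy exactly Poisson — the regime the digital-PCR
    estimators (and their confidence intervals) assume.
    """
    rng = np.random.default_rng(seed)
    return [
        MoleculeSpecies(sp.name, sp.channels, int(rng.poisson(sp.copies)))
        for sp in species
    ]


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_BASE_ARR[rng.integers(4, size=length)])


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, constant Q40)


def write_fastq(reads: list[str], path: str, prefix: str = "read") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"{prefix}{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]


def read_fasta(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]


# ---------------------------------------------------------------------------
# default synthetic locus: the study conditions for coverage analyses


#: Haplotype distribution over 6 upstream + 6 downstream flanking SNPs.
#: Two major fully coupled haplotypes dominate (strong LD across the locus,
#: as at a real disease gene), plus recombinant minors that decouple the
#: two flanks so that different SNP pairs cover different individuals.
DEFAULT_LOCUS_HAPLOTYPES = {
    "000000000000": 0.34,
    "111111111111": 0.26,
    "000000111111": 0.10,
    "111111000000": 0.08,
    "001111111111": 0.07,
    "111100000011": 0.05,
    "000011110000": 0.05,
    "110000001111": 0.03,
    "101010010101": 0.02,
}

#: 40-kb gene body, 50-kb flanks either side.
DEFAULT_GENE = GenomicInterval("chr8", 100_000, 140_000, "GENE")

#: Neighboring co-regulated gene upstream of the target; therapy options
#: whose excision interval overlaps it are excluded.
DEFAULT_EXCLUSION = GenomicInterval("chr8", 55_000, 70_000, "NEIGHBOR")

#: SNP positions: 6 upstream of the gene (two of them beyond the neighbor
#: gene boundary, exercising the exclusion rule) and 6 downstream.
DEFAULT_LOCUS_POSITIONS = [
    52_000, 60_000, 75_000, 85_000, 92_000, 98_000,
    141_000, 145_000, 152_000, 160_000, 175_000, 185_000,
]

#: Invariant (bi-allelic) cut site inside intron 1 of the gene.
DEFAULT_BIALLELIC_CUT = 102_000


def simulate_locus_panel(
    n_individuals: int = 2548, seed: int = 0
) -> tuple[PhasedPanel, TruthRecord]:
    """Panel over the default synthetic disease-gene locus.

    The default cohort size matches the phased reference panel used for
    the coverage analyses (2,548 individuals).
    """
    return simulate_panel(
        n_individuals,
        DEFAULT_LOCUS_HAPLOTYPES,
        seed,
        positions=DEFAULT_LOCUS_POSITIONS,
    )
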