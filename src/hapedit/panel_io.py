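"""Phased haplotype panels and the interval/mutation tables built on top of them.

The central container is :class:`PhasedPanel`: a ``(2 * n_individuals,
n_sites)`` matrix of 0/1 alleles over biallelic SNPs, with rows ``2k`` and
``2k + 1`` holding the two phased haplotypes of individual ``k``.  All
population-coverage computations (heterozygosity, double-heterozygote
counting, greedy therapy selection) operate on this matrix.

Coordinate conventions
----------------------
Internally every position is 0-based and intervals are half-open
``[start, end)`` (BED semantics).  VCF positions are 1-based and converted
on read/write.  Flank geometry for :func:`filter_common_flanking_sites`:
the upstream flank is ``[gene.start - flank_bp, gene.start)`` and the
downstream flank is ``[gene.end, gene.end + flank_bp)`` in internal
coordinates, i.e. the first base after the gene body belongs to the
downstream flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel or one of its on-disk sources violates a contract."""


class EmptyPanelError(PanelError):
    """No sites survived the configured filters."""


@dataclass(frozen=True)
class SNPSite:
    """A biallelic SNP with its alt-allele frequency in the current panel."""

    id: str
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    alt_frequency: float

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise PanelError(
                f"{self.id}: alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.id}: ref and alt alleles are identical")
        if not 0.0 <= self.alt_frequency <= 1.0:
            raise PanelError(f"{self.id}: alt_frequency {self.alt_frequency} outside [0, 1]")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"interval {self.label or self.chrom}: start {self.start} >= end {self.end}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhasedPanel:
    """Phased haplotypes of a cohort over an ordered list of biallelic SNPs."""

    sites: list[SNPSite]
    sample_ids: list[str]
    haplotypes: np.ndarray  # (2 * n_individuals, n_sites) of {0, 1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D")
        n_hap, n_sites = self.haplotypes.shape
        if n_hap != 2 * len(self.sample_ids):
            raise PanelError(
                f"haplotype rows ({n_hap}) != 2 x samples ({len(self.sample_ids)})"
            )
        if n_sites != len(self.sites):
            raise PanelError(f"haplotype columns ({n_sites}) != sites ({len(self.sites)})")
        vals = np.unique(self.haplotypes)
        if not np.all(np.isin(vals, (0, 1))):
            raise PanelError(f"haplotype entries must be 0/1, found {vals}")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise PanelError("duplicate (chrom, pos) among sites")
        if keys != sorted(keys):
            raise PanelError("sites must be sorted by (chrom, pos)")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def alt_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site, recomputed from the matrix."""
        if self.haplotypes.shape[0] == 0:
            return np.zeros(self.n_sites)
        return self.haplotypes.mean(axis=0)

    def validate_frequencies(self, atol: float = 1e-12) -> None:
        stored = np.array([s.alt_frequency for s in self.sites])
        recomputed = self.alt_frequencies()
        if not np.allclose(stored, recomputed, atol=atol, rtol=0):
            bad = int(np.argmax(np.abs(stored - recomputed)))
            raise PanelError(
                f"stored alt_frequency of site {self.sites[bad].id} "
                f"({stored[bad]}) does not match matrix ({recomputed[bad]})"
            )

    def with_recomputed_frequencies(self) -> "PhasedPanel":
        freqs = self.alt_frequencies()
        sites = [replace(s, alt_frequency=float(f)) for s, f in zip(self.sites, freqs)]
        return PhasedPanel(sites, list(self.sample_ids), self.haplotypes.copy())

    def subset_sites(self, indices) -> "PhasedPanel":
        """Panel restricted to the given site columns (frequencies recomputed)."""
        indices = list(indices)
        sites = [self.sites[i] for i in indices]
        return PhasedPanel(sites, list(self.sample_ids), self.haplotypes[:, indices].copy())


@dataclass(frozen=True)
class MutationTable:
    """Disease mutations with nonnegative prevalence weights (sum > 0)."""

    mutation_ids: tuple[str, ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mutation_ids:
            raise PanelError("mutation table must contain at least one row")
        weights = self.weights or tuple(1.0 for _ in self.mutation_ids)
        object.__setattr__(self, "weights", weights)
        if len(weights) != len(self.mutation_ids):
            raise PanelError("weights length mismatch")
        if any(w < 0 for w in weights):
            raise PanelError("prevalence weights must be nonnegative")
        if sum(weights) <= 0:
            raise PanelError("prevalence weights must sum to a positive value")

    @classmethod
    def uniform(cls, n: int, prefix: str = "mut") -> "MutationTable":
        return cls(tuple(f"{prefix}{i + 1}" for i in range(n)))


# ---------------------------------------------------------------------------
# readers / writers


def read_phased_vcf(
    path: str,
    region: GenomicInterval | None = None,
    unphased_policy: str = "drop_site",
) -> PhasedPanel:
    """Load biallelic, fully phased SNPs from a VCF into a :class:`PhasedPanel`.

    Multi-allelic records, indels/MNPs and (under the default policy) sites
    with any unphased or missing genotype are skipped; skip counts are
    logged.  ``unphased_policy`` is one of ``"drop_site"`` (default) or
    ``"drop_individuals"`` (removes every individual that is unphased or
    missing at *any* retained site).  Alt frequencies are recomputed from
    the retained haplotypes, not taken from INFO/AF.
    """
    if unphased_policy not in ("drop_site", "drop_individuals"):
        raise PanelError(f"unknown unphased_policy {unphased_policy!r}")
    try:
        vcf = VCF(path)
    except OSError as exc:  # cyvcf2 raises OSError on missing/unreadable files
        raise OSError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise PanelError(f"VCF {path!r} has no samples")

    records = vcf
    in_region = None
    if region is not None:
        if str(path).endswith((".gz", ".bgz")):  # tabix-indexed random access
            records = vcf(f"{region.chrom}:{region.start + 1}-{region.end}")
        else:  # plain-text VCF: scan and filter
            in_region = region
    sites: list[tuple[str, int, str, str]] = []
    columns: list[np.ndarray] = []
    bad_individuals = np.zeros(n, dtype=bool)
    n_multi = n_nonsnp = n_unphased = 0
    for rec in records:
        if in_region is not None and not (
            rec.CHROM == in_region.chrom and in_region.start < rec.POS <= in_region.end
        ):
            continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_nonsnp += 1
            continue
        # genotypes: rows of [allele_a, allele_b, phased_flag]
        gts = np.array(rec.genotypes, dtype=np.int64)
        ok = (gts[:, 2] == 1) & (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
        if not ok.all():
            n_unphased += 1
            if unphased_policy == "drop_site":
                continue
            bad_individuals |= ~ok
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        sites.append((vid, rec.CHROM, rec.POS - 1, ref, alt))
        col = np.empty(2 * n, dtype=np.int8)
        col[0::2] = np.clip(gts[:, 0], 0, 1)
        col[1::2] = np.clip(gts[:, 1], 0, 1)
        columns.append(col)
    if n_multi or n_nonsnp or n_unphased:
        logger.info(
            "read_phased_vcf(%s): skipped %d multi-allelic, %d non-SNP records; "
            "%d sites had unphased/missing genotypes (policy=%s)",
            path, n_multi, n_nonsnp, n_unphased, unphased_policy,
        )
    if not sites:
        raise EmptyPanelError(
            f"no sites left in {path!r} after filters "
            f"(biallelic SNP, fully phased, region={region})"
        )

    hap = np.stack(columns, axis=1)
    if unphased_policy == "drop_individuals" and bad_individuals.any():
        keep = ~bad_individuals
        logger.info("dropping %d individuals with unphased/missing genotypes",
                    int(bad_individuals.sum()))
        samples = [s for s, k in zip(samples, keep) if k]
        if not samples:
            raise EmptyPanelError(f"no fully phased individuals left in {path!r}")
        hap = hap[np.repeat(keep, 2)]

    order = sorted(range(len(sites)), key=lambda i: (sites[i][1], sites[i][2]))
    freqs = hap.mean(axis=0)
    site_objs = [
        SNPSite(*sites[i], alt_frequency=float(freqs[i])) for i in order
    ]
    panel = PhasedPanel(site_objs, samples, hap[:, order])
    logger.info("read_phased_vcf(%s): %d sites x %d individuals",
                path, panel.n_sites, panel.n_individuals)
    return panel


def write_panel(panel: PhasedPanel, path: str) -> None:
    """Write a panel as a minimal phased VCF (lossless round-trip dialect).

    Emits ``GT`` only, phased with ``|``, positions converted back to
    1-based; column order is fixed so output is byte-deterministic.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in panel.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, site in enumerate(panel.sites):
            col = panel.haplotypes[:, j]
            gts = "\t".join(
                f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(panel.n_individuals)
            )
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t{site.id}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_common_flanking_sites(
    panel: PhasedPanel,
    gene: GenomicInterval,
    flank_bp: int = 50_000,
    af_min: float = 0.1,
    af_max: float = 0.9,
) -> tuple[list[int], list[int]]:
    """Indices of common SNPs in the two ``flank_bp`` windows around a gene.

    A site qualifies when ``af_min < alt_frequency < af_max`` (strict, so a
    site at exactly the boundary frequency is excluded) and its position
    lies in ``[gene.start - flank_bp, gene.start)`` (upstream) or
    ``[gene.end, gene.end + flank_bp)`` (downstream).  Returns
    ``(upstream_indices, downstream_indices)`` into ``panel.sites``.
    """
    if flank_bp <= 0:
        raise PanelError(f"flank_bp must be positive, got {flank_bp}")
    if not 0 <= af_min < af_max <= 1:
        raise PanelError(f"invalid AF bounds ({af_min}, {af_max})")
    chroms = {s.chrom for s in panel.sites}
    if gene.chrom not in chroms:
        raise PanelError(
            f"gene interval on {gene.chrom!r} but panel covers {sorted(chroms)}"
        )
    upstream: list[int] = []
    downstream: list[int] = []
    for i, s in enumerate(panel.sites):
        if s.chrom != gene.chrom or not af_min < s.alt_frequency < af_max:
            continue
        if gene.start - flank_bp <= s.pos < gene.start:
            upstream.append(i)
        elif gene.end <= s.pos < gene.end + flank_bp:
            downstream.append(i)
    return upstream, downstream


def read_intervals(path: str) -> list[GenomicInterval]:
    """Parse a BED file (0-based half-open) into labelled intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, label))
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_intervals(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_mutation_table(path: str) -> MutationTable:
    """Read a mutation prevalence TSV with columns ``mutation_id`` and
    (optionally) ``prevalence_weight``; missing weights default to 1."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise PanelError(f"mutation table {path!r} is empty")
    if "mutation_id" not in df.columns:
        raise PanelError(f"mutation table {path!r} lacks a 'mutation_id' column")
    ids = tuple(str(m) for m in df["mutation_id"])
    if "prevalence_weight" in df.columns:
        weights = tuple(float(w) for w in df["prevalence_weight"])
    else:
        weights = tuple(1.0 for _ in ids)
    return MutationTable(ids, weights)


def write_mutation_table(table: MutationTable, path: str) -> None:
    pd.DataFrame(
        {"mutation_id": table.mutation_ids, "prevalence_weight": table.weights}
    ).to_csv(path, sep="\t", index=False)
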