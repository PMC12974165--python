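"""Population-coverage design of allele-specific excision therapies.

Given a phased panel, a disease-gene interval and its common flanking SNPs,
this module answers: *how many distinct guide-pair reagents are needed to
offer an allele-specific excision to a given fraction of the population?*

Three strategies are compared:

* ``mutation_specific`` — one bespoke reagent per causative mutation;
  coverage accumulates by mutation prevalence (analytic, no panel needed).
* ``snp_pair`` — two allele-specific guides on common SNPs flanking the
  gene; an individual is covered by a pair iff heterozygous at *both*
  SNPs (phase is deliberately ignored: guides exist for either allele).
* ``single_snp_plus_biallelic`` — one allele-specific guide on a flanking
  SNP plus one invariant guide cutting inside the gene; an individual is
  covered iff heterozygous at the single SNP.

Candidate reagents whose excision interval would remove a neighboring gene
are excluded.  Selection is greedy maximum coverage: at each step pick the
option heterozygous in the most not-yet-covered individuals, remove them,
repeat — with ties broken toward the smaller excision span, then the
lexicographically smaller label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import GenomicInterval, MutationTable, PanelError, PhasedPanel, SNPSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNPPair:
    """A 5' / 3' flanking SNP pair and the interval its excision removes."""

    left: SNPSite
    right: SNPSite

    def __post_init__(self) -> None:
        if self.left.pos >= self.right.pos:
            raise PanelError("pair sites must satisfy left.pos < right.pos")

    @property
    def excision_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.left.chrom, self.left.pos, self.right.pos + 1,
            f"{self.left.id}-{self.right.id}",
        )


@dataclass(frozen=True)
class TherapyOption:
    """One candidate molecular therapy and the individuals it can treat."""

    kind: str  # mutation_specific | snp_pair | single_snp_plus_biallelic
    label: str
    covered: frozenset  # individual indices
    excision_interval: GenomicInterval | None = None

    @property
    def span(self) -> int:
        return self.excision_interval.length if self.excision_interval else 0

    @property
    def n_covered(self) -> int:
        return len(self.covered)


@dataclass(frozen=True)
class CoveragePoint:
    therapy_count: int
    cumulative_fraction: float
    option: TherapyOption | None = None


@dataclass
class CoverageCurve:
    """Cumulative population coverage as therapies accumulate."""

    points: list[CoveragePoint]
    strategy: str = ""

    def __post_init__(self) -> None:
        fracs = [p.cumulative_fraction for p in self.points]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("coverage curve must be nondecreasing")
        if any(f > 1 + 1e-12 for f in fracs):
            raise ValueError("coverage fraction exceeds 1")

    def fraction_at(self, k: int) -> float:
        """Cumulative fraction after the first ``k`` therapies."""
        frac = 0.0
        for p in self.points:
            if p.therapy_count <= k:
                frac = p.cumulative_fraction
        return frac

    def therapies_to_exceed(self, fraction: float) -> int | None:
        """Smallest therapy count with coverage strictly above ``fraction``."""
        for p in self.points:
            if p.cumulative_fraction > fraction:
                return p.therapy_count
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "therapy_count": [p.therapy_count for p in self.points],
                "cumulative_fraction": [p.cumulative_fraction for p in self.points],
                "target_description": [p.option.label if p.option else "" for p in self.points],
            }
        )


@dataclass(frozen=True)
class PhaseCall:
    """Maximum-likelihood phasing of a multi-site heterozygote."""

    hap_a: str
    hap_b: str
    log_likelihood_ratio: float  # best vs. runner-up; inf when unique
    method: str = "panel_haplotype_frequencies"


# ---------------------------------------------------------------------------
# heterozygosity


def het_matrix(panel: PhasedPanel) -> np.ndarray:
    """Boolean (n_individuals, n_sites) matrix of heterozygosity."""
    return panel.haplotypes[0::2] != panel.haplotypes[1::2]


def site_heterozygosity(panel: PhasedPanel, site_index: int) -> float:
    """Fraction of individuals whose two haplotypes differ at the site."""
    col = panel.haplotypes[:, site_index]
    return float(np.mean(col[0::2] != col[1::2]))


def pair_double_het_matrix(
    panel: PhasedPanel, upstream_sites: list[int], downstream_sites: list[int]
) -> pd.DataFrame:
    """Fraction of individuals heterozygous at both members of each pair.

    Rows are upstream sites, columns downstream sites, labelled by SNP id
    (ready to dump as TSV for heatmap rendering).
    """
    if not upstream_sites or not downstream_sites:
        raise PanelError("site lists must be non-empty")
    if set(upstream_sites) & set(downstream_sites):
        raise PanelError("site lists must be disjoint")
    het = het_matrix(panel)
    up = het[:, upstream_sites].astype(float)
    down = het[:, downstream_sites].astype(float)
    mat = up.T @ down / panel.n_individuals
    return pd.DataFrame(
        mat,
        index=[panel.sites[i].id for i in upstream_sites],
        columns=[panel.sites[j].id for j in downstream_sites],
    )


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidate_therapies(
    panel: PhasedPanel,
    gene: GenomicInterval,
    flanks: tuple[list[int], list[int]],
    kind: str = "snp_pair",
    exclusion_intervals: tuple[GenomicInterval, ...] = (),
    biallelic_cut_position: int | None = None,
    require_gene_span: bool = True,
) -> list[TherapyOption]:
    """All valid therapy options of one kind, each with its covered set.

    An option is dropped iff its excision interval overlaps any exclusion
    interval (e.g. a neighboring gene), or — for pairs, by default — fails
    to span the whole gene body.
    """
    up_idx, down_idx = flanks
    het = het_matrix(panel)
    options: list[TherapyOption] = []

    if kind == "snp_pair":
        if not up_idx or not down_idx:
            raise PanelError("snp_pair enumeration needs both flank site lists")
        for i in up_idx:
            for j in down_idx:
                pair = SNPPair(panel.sites[i], panel.sites[j])
                interval = pair.excision_interval
                if require_gene_span and not (
                    interval.start <= gene.start and gene.end <= interval.end
                ):
                    continue
                if any(interval.overlaps(x) for x in exclusion_intervals):
                    continue
                covered = frozenset(np.flatnonzero(het[:, i] & het[:, j]).tolist())
                options.append(TherapyOption("snp_pair", interval.label, covered, interval))
    elif kind == "single_snp_plus_biallelic":
        if biallelic_cut_position is None:
            raise PanelError("single_snp_plus_biallelic needs a bi-allelic cut position")
        if not gene.start < biallelic_cut_position < gene.end:
            raise PanelError("bi-allelic cut position must lie inside the gene")
        for i in [*up_idx, *down_idx]:
            site = panel.sites[i]
            lo = min(site.pos, biallelic_cut_position)
            hi = max(site.pos, biallelic_cut_position)
            interval = GenomicInterval(site.chrom, lo, hi, f"{site.id}+BA")
            if any(interval.overlaps(x) for x in exclusion_intervals):
                continue
            covered = frozenset(np.flatnonzero(het[:, i]).tolist())
            options.append(
                TherapyOption("single_snp_plus_biallelic", interval.label, covered, interval)
            )
    else:
        raise PanelError(f"unknown therapy kind {kind!r}")

    if not options:
        logger.warning("enumerate_candidate_therapies: every %s candidate was excluded", kind)
    return options


# ---------------------------------------------------------------------------
# greedy maximum-coverage selection


def greedy_key(option: TherapyOption, already_covered: frozenset):
    """Sort key of one greedy step: maximal gain, then smaller excision
    span, then lexicographic label."""
    gain = len(option.covered - already_covered)
    return (-gain, option.span, option.label)


def greedy_select(
    options: list[TherapyOption],
    n_individuals: int,
    target_coverage: float | None = None,
    max_therapies: int | None = None,
    count_per_guide: bool = False,
) -> CoverageCurve:
    """Greedy maximum-coverage selection of therapy options.

    At each step the option covering the most not-yet-covered individuals
    is chosen and those individuals removed from consideration; stops when
    cumulative coverage exceeds ``target_coverage``, ``max_therapies`` is
    reached, or no option adds coverage.  ``count_per_guide`` makes a
    two-guide SNP pair cost two therapy units instead of one.
    """
    if not options:
        raise PanelError("no candidate options to select from")
    if target_coverage is None and max_therapies is None:
        raise PanelError("at least one stopping rule required")
    covered: frozenset = frozenset()
    remaining = list(options)
    points: list[CoveragePoint] = []
    count = 0
    while remaining:
        best = min(remaining, key=lambda o: greedy_key(o, covered))
        gain = len(best.covered - covered)
        if gain == 0:
            break
        covered = covered | best.covered
        remaining.remove(best)
        cost = 2 if (count_per_guide and best.kind == "snp_pair") else 1
        count += cost
        points.append(CoveragePoint(count, len(covered) / n_individuals, best))
        if target_coverage is not None and points[-1].cumulative_fraction >= target_coverage:
            break
        if max_therapies is not None and count >= max_therapies:
            break
    return CoverageCurve(points, strategy="greedy")


def coverage_curve_mutation_uniform(
    n_mutations: int | None = None, weights: MutationTable | None = None
) -> CoverageCurve:
    """Coverage curve for mutation-specific therapies ordered by prevalence.

    With uniform weights the fraction after ``k`` therapies is ``k / n``;
    with a prevalence table, therapies are sorted by descending weight and
    the fraction is the cumulative weight share.
    """
    if weights is None:
        if n_mutations is None or n_mutations < 1:
            raise PanelError("need n_mutations >= 1 or a weight table")
        weights = MutationTable.uniform(n_mutations)
    order = sorted(
        range(len(weights.mutation_ids)),
        key=lambda i: (-weights.weights[i], weights.mutation_ids[i]),
    )
    total = sum(weights.weights)
    points = []
    cum = 0.0
    for k, i in enumerate(order, start=1):
        cum += weights.weights[i]
        opt = TherapyOption("mutation_specific", weights.mutation_ids[i], frozenset())
        points.append(CoveragePoint(k, cum / total, opt))
    return CoverageCurve(points, strategy="mutation_specific")


# ---------------------------------------------------------------------------
# phasing from panel haplotype frequencies


def infer_phase(
    panel: PhasedPanel, het_site_indices: list[int], max_het_sites: int = 16
) -> PhaseCall:
    """Phase a multi-site heterozygote from panel haplotype frequencies.

    Enumerates all ``2**(h-1)`` phasings of a genotype heterozygous at the
    given sites, scores each by the product of the panel frequencies of its
    two implied haplotypes (pseudocount ``1/(2N+1)`` for haplotypes unseen
    in the panel), and returns the maximum-likelihood phasing with the
    log-likelihood ratio over the runner-up.
    """
    h = len(het_site_indices)
    if h == 0:
        raise PanelError("no heterozygous sites given")
    if h > max_het_sites:
        raise PanelError(f"{h} het sites exceeds capacity ({max_het_sites})")
    cols = panel.haplotypes[:, het_site_indices]
    n_hap = cols.shape[0]
    pseudo = 1.0 / (n_hap + 1)
    counts: dict[str, int] = {}
    for row in cols:
        key = "".join(map(str, row))
        counts[key] = counts.get(key, 0) + 1

    def freq(hap: str) -> float:
        c = counts.get(hap, 0)
        return c / n_hap if c else pseudo

    if h == 1:
        return PhaseCall("0", "1", math.inf)

    scored = []
    for code in range(2 ** (h - 1)):
        hap_a = "0" + format(code, f"0{h - 1}b")
        hap_b = "".join("1" if c == "0" else "0" for c in hap_a)
        loglik = math.log(freq(hap_a)) + math.log(freq(hap_b))
        scored.append((loglik, hap_a, hap_b))
    scored.sort(key=lambda t: (-t[0], t[1]))
    best = scored[0]
    if len(scored) == 1:
        return PhaseCall(best[1], best[2], math.inf)
    ratio = best[0] - scored[1][0]
    if all(counts.get(a, 0) == 0 and counts.get(b, 0) == 0 for _, a, b in scored):
        logger.warning("infer_phase: no phasing supported by panel haplotypes")
        ratio = 0.0
    return PhaseCall(best[1], best[2], ratio)


# ---------------------------------------------------------------------------
# whole-locus analysis (shared by the synthetic locus and external panels)


def reproduce_locus_analysis(
    vcf_path: str,
    gene: GenomicInterval,
    exclusion_intervals: tuple[GenomicInterval, ...] = (),
    biallelic_cut_position: int | None = None,
    flank_bp: int = 50_000,
) -> dict:
    """Run the full coverage analysis on an external phased panel.

    Reads the gene ± flank region from a (preferably tabix-indexed) phased
    VCF — e.g. a 1000 Genomes chromosome file — and returns the
    :func:`analyze_locus` report.  The gene boundary coordinates used are
    echoed in the result, since flank SNP counts are sensitive to them.
    """
    from .panel_io import read_phased_vcf

    region = GenomicInterval(
        gene.chrom, max(0, gene.start - flank_bp), gene.end + flank_bp, "locus"
    )
    panel = read_phased_vcf(vcf_path, region=region)
    out = analyze_locus(
        panel, gene, exclusion_intervals, biallelic_cut_position, flank_bp
    )
    out["gene"] = (gene.chrom, gene.start, gene.end)
    return out


def analyze_locus(
    panel: PhasedPanel,
    gene: GenomicInterval,
    exclusion_intervals: tuple[GenomicInterval, ...] = (),
    biallelic_cut_position: int | None = None,
    flank_bp: int = 50_000,
    af_min: float = 0.1,
    af_max: float = 0.9,
    pair_target: float = 0.5,
    single_target: float = 0.75,
    n_mutations: int = 51,
    mutation_target: float = 0.5,
) -> dict:
    """End-to-end coverage comparison of the three therapy strategies.

    Returns a dict with the flank SNP counts, the per-strategy coverage
    curves, and the smallest therapy count exceeding each strategy's
    target coverage.
    """
    from .panel_io import filter_common_flanking_sites

    up, down = filter_common_flanking_sites(panel, gene, flank_bp, af_min, af_max)
    out: dict = {
        "n_individuals": panel.n_individuals,
        "n_upstream_sites": len(up),
        "n_downstream_sites": len(down),
        "n_common_sites": len(up) + len(down),
    }
    mut_curve = coverage_curve_mutation_uniform(n_mutations)
    out["mutation_curve"] = mut_curve
    out["mutation_therapies"] = mut_curve.therapies_to_exceed(mutation_target)

    pair_options = enumerate_candidate_therapies(
        panel, gene, (up, down), "snp_pair", exclusion_intervals
    )
    out["n_pair_options"] = len(pair_options)
    if pair_options:
        pair_curve = greedy_select(pair_options, panel.n_individuals, target_coverage=None,
                                   max_therapies=len(pair_options))
        out["pair_curve"] = pair_curve
        out["pair_therapies"] = pair_curve.therapies_to_exceed(pair_target)

    if biallelic_cut_position is not None:
        single_options = enumerate_candidate_therapies(
            panel, gene, (up, down), "single_snp_plus_biallelic",
            exclusion_intervals, biallelic_cut_position,
        )
        out["n_single_options"] = len(single_options)
        if single_options:
            single_curve = greedy_select(
                single_options, panel.n_individuals, target_coverage=None,
                max_therapies=len(single_options),
            )
            out["single_curve"] = single_curve
            out["single_therapies"] = single_curve.therapies_to_exceed(single_target)
    return out
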