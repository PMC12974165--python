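"""Digital-PCR quantification of excision, inversion and allele specificity.

Partition-level fluorophore positivity is summarised into per-channel mean
occupancies via the standard digital-PCR Poisson inversion
``lambda = -ln(1 - k/n)`` and combined into the assay quantities:

* gain-of-signal excision / inversion frequency — the edit-junction
  concentration normalised to a two-copy reference locus (RPP30), reported
  as percent of alleles; 50% is the ceiling for perfectly allele-specific
  editing,
* loss-of-signal excision frequency — disappearance of an intact internal
  amplicon relative to the reference,
* fractional abundance — ``lambda_A / (lambda_A + lambda_B)`` of two
  probe-distinguished alleles in one reaction,
* expression ratio — FAM-positive over HEX-positive partitions (raw droplet
  ratio, as reported by the instrument software) or the Poisson-corrected
  ratio,
* multiplexed 4-color excision frequency + specificity, where partitions
  positive for the excision probe and exactly one allele probe attribute
  the edit to an allele, and ambiguous triple-positive partitions are
  excluded (warning when they exceed 10% of edit-positive partitions).

Two estimation modes are available throughout: ``"raw"`` (ratios of
positive-partition counts, the formulas as stated for the plate reader)
and ``"poisson"`` (ratios of Poisson-corrected occupancies, preferred at
high loading).  Confidence intervals are delta-method propagations of the
binomial variance of each positive fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import CHANNELS

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DpcrError(ValueError):
    pass


class SaturationError(DpcrError):
    """All partitions positive: occupancy unidentifiable, dilute and re-run."""


class UndefinedRatioError(DpcrError):
    pass


class UndefinedSpecificityError(DpcrError):
    pass


@dataclass(frozen=True)
class ChannelCount:
    """Positive-partition count for one channel of one reaction."""

    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise DpcrError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise DpcrError(f"n_positive {self.n_positive} outside [0, {self.n_total}]")


@dataclass(frozen=True)
class LambdaEstimate:
    """Mean copies per partition with a delta-method standard error."""

    value: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (max(0.0, self.value - Z95 * self.se), self.value + Z95 * self.se)


@dataclass
class QuantResult:
    """A frequency (percent) or ratio with its 95% CI and provenance."""

    frequency_pct: float
    ci: tuple[float, float]
    mode: str
    lambdas: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frequency_pct < 0:
            raise DpcrError("frequency must be nonnegative")
        lo, hi = self.ci
        if not lo - 1e-12 <= self.frequency_pct <= hi + 1e-12:
            raise DpcrError("CI must contain the point estimate")


@dataclass
class SpecificityResult:
    """Fraction of edits attributed to the target allele."""

    target_fraction: float
    excluded_triple_fraction: float
    counts: dict
    warning: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise DpcrError("target_fraction outside [0, 1]")
        self.warning = self.excluded_triple_fraction >= 0.10


# ---------------------------------------------------------------------------
# Poisson occupancy


def poisson_lambda(n_positive: int, n_total: int) -> LambdaEstimate:
    """Mean copies/partition from a positive-partition count.

    ``lambda = -ln(1 - p)`` with ``p = n_positive / n_total``; the standard
    error is the delta-method propagation ``sqrt(p / ((1 - p) n))``.
    """
    cc = ChannelCount(n_positive, n_total)
    if cc.n_positive == cc.n_total:
        raise SaturationError(
            f"all {n_total} partitions positive; occupancy is unbounded — dilute and re-run"
        )
    p = cc.n_positive / cc.n_total
    lam = -math.log1p(-p)
    se = math.sqrt(p / ((1.0 - p) * cc.n_total))
    return LambdaEstimate(lam, se)


def _as_channel_count(x) -> ChannelCount:
    if isinstance(x, ChannelCount):
        return x
    n_pos, n_tot = x
    return ChannelCount(int(n_pos), int(n_tot))


def _ratio_with_se(num, den, mode: str) -> tuple[float, float, dict]:
    """(ratio, se, lambdas) of two channel counts under either mode."""
    num, den = _as_channel_count(num), _as_channel_count(den)
    if mode == "poisson":
        le, lr = poisson_lambda(num.n_positive, num.n_total), poisson_lambda(
            den.n_positive, den.n_total
        )
        lambdas = {"numerator": le, "denominator": lr}
        if lr.value == 0:
            raise UndefinedRatioError("reference occupancy is zero")
        r = le.value / lr.value
        if le.value == 0:
            return 0.0, 0.0, lambdas
        rel = (le.se / le.value) ** 2 + (lr.se / lr.value) ** 2
        return r, r * math.sqrt(rel), lambdas
    if mode == "raw":
        if den.n_positive == 0:
            raise UndefinedRatioError("no positive reference partitions")
        pe, pr = num.n_positive / num.n_total, den.n_positive / den.n_total
        r = pe / pr
        if pe == 0:
            return 0.0, 0.0, {}
        rel = (1 - pe) / (num.n_total * pe) + (1 - pr) / (den.n_total * pr)
        return r, r * math.sqrt(max(rel, 0.0)), {}
    raise DpcrError(f"unknown mode {mode!r}")


def _lambda_values(lambdas: dict) -> dict:
    return {k: v.value for k, v in lambdas.items()}


# ---------------------------------------------------------------------------
# assay quantities


def excision_frequency_gain(
    edit_counts,
    ref_counts,
    ref_copies_per_genome: int = 2,
    alleles_per_genome: int = 2,
    mode: str = "poisson",
) -> QuantResult:
    """Gain-of-signal excision frequency, percent of alleles.

    ``100 * (lambda_edit / lambda_ref) * (ref_copies_per_genome /
    alleles_per_genome)``; with the defaults, perfectly allele-specific
    editing tops out at 50%.
    """
    scale = 100.0 * ref_copies_per_genome / alleles_per_genome
    r, se, lambdas = _ratio_with_se(edit_counts, ref_counts, mode)
    f = scale * r
    ci = (max(0.0, f - Z95 * scale * se), f + Z95 * scale * se)
    return QuantResult(f, ci, mode, _lambda_values(lambdas))


def inversion_frequency(
    inv_counts,
    ref_counts,
    ref_copies_per_genome: int = 2,
    alleles_per_genome: int = 2,
    mode: str = "poisson",
) -> QuantResult:
    """Gain-of-signal inversion frequency (same contract as excision gain)."""
    return excision_frequency_gain(
        inv_counts, ref_counts, ref_copies_per_genome, alleles_per_genome, mode
    )


def excision_frequency_loss(internal_counts, ref_counts, mode: str = "poisson") -> QuantResult:
    """Loss-of-signal excision frequency: ``100 * (1 - lambda_int / lambda_ref)``.

    Negative point estimates (internal amplicon apparently above the
    reference) are clamped to zero with a warning.
    """
    r, se, lambdas = _ratio_with_se(internal_counts, ref_counts, mode)
    f = 100.0 * (1.0 - r)
    warnings = []
    if f < 0:
        warnings.append(f"negative excision estimate {f:.3f}% clamped to 0")
        f = 0.0
    ci = (max(0.0, f - Z95 * 100.0 * se), max(f, f + Z95 * 100.0 * se))
    return QuantResult(f, ci, mode, _lambda_values(lambdas), warnings)


@dataclass
class FractionalAbundance:
    fraction: float
    ci: tuple[float, float]
    mode: str


def fractional_abundance(a_counts, b_counts, mode: str = "poisson") -> FractionalAbundance:
    """Fraction of allele A: ``lambda_A / (lambda_A + lambda_B)``.

    Symmetric inputs give exactly 0.5 (an unedited heterozygote control).
    """
    a, b = _as_channel_count(a_counts), _as_channel_count(b_counts)
    if mode == "poisson":
        la, lb = poisson_lambda(a.n_positive, a.n_total), poisson_lambda(b.n_positive, b.n_total)
        va, vb = la.se ** 2, lb.se ** 2
        xa, xb = la.value, lb.value
    elif mode == "raw":
        xa, xb = a.n_positive / a.n_total, b.n_positive / b.n_total
        va = xa * (1 - xa) / a.n_total
        vb = xb * (1 - xb) / b.n_total
    else:
        raise DpcrError(f"unknown mode {mode!r}")
    s = xa + xb
    if s == 0:
        raise UndefinedRatioError("both channels empty; fractional abundance undefined")
    fa = xa / s
    se = math.sqrt(xb * xb * va + xa * xa * vb) / (s * s)
    return FractionalAbundance(fa, (max(0.0, fa - Z95 * se), min(1.0, fa + Z95 * se)), mode)


def expression_ratio(gene_counts, housekeeping_counts, mode: str = "raw_ratio") -> QuantResult:
    """Expression of a gene relative to a housekeeping control.

    ``raw_ratio`` divides positive-partition counts (the droplet-count
    ratio as reported); ``poisson`` divides corrected occupancies.
    """
    inner = {"raw_ratio": "raw", "poisson": "poisson"}.get(mode)
    if inner is None:
        raise DpcrError(f"unknown mode {mode!r}")
    r, se, lambdas = _ratio_with_se(gene_counts, housekeeping_counts, inner)
    return QuantResult(r, (max(0.0, r - Z95 * se), r + Z95 * se), mode, _lambda_values(lambdas))


# ---------------------------------------------------------------------------
# partition classification (multiplex)


def signature_key(channels) -> str:
    """Canonical ``+``-joined signature, ``"NEG"`` for the all-negative class."""
    chan_set = set(channels)
    chans = [c for c in CHANNELS if c in chan_set]
    return "+".join(chans) if chans else "NEG"


def multiplex_classify(table: pd.DataFrame) -> dict:
    """Exact counts of every ``2**k`` channel signature in a boolean table.

    The input is dialect A: a ``partition_id`` column plus one 0/1 column
    per channel.  All signatures are present in the result (zero-filled);
    counts sum to the number of partitions.
    """
    channels = [c for c in table.columns if c != "partition_id"]
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise DpcrError(f"unknown channels {sorted(unknown)}; expected subset of {CHANNELS}")
    counts: dict[str, int] = {}
    n = len(table)
    if n:
        mat = table[channels].to_numpy(dtype=bool)
        # encode each partition's signature as a bitmask
        weights = 1 << np.arange(len(channels))
        codes = mat @ weights
        found = np.bincount(codes, minlength=1 << len(channels))
    else:
        found = np.zeros(1 << len(channels), dtype=int)
    for code in range(1 << len(channels)):
        sig = signature_key(c for k, c in enumerate(channels) if code >> k & 1)
        counts[sig] = int(found[code])
    return counts


class PartitionCounts:
    """Fluorophore-positivity counts over the partitions of one reaction.

    Holds summary counts per signature class (dialect B); build from a
    per-partition boolean table (dialect A) with :meth:`from_table`.
    """

    def __init__(self, class_counts: dict, channels=None, n_partitions: int | None = None):
        chans: set[str] = set()
        for sig in class_counts:
            if sig != "NEG":
                chans.update(sig.split("+"))
        unknown = chans - set(CHANNELS)
        if unknown:
            raise DpcrError(f"unknown channels {sorted(unknown)}")
        self.channels = tuple(c for c in CHANNELS if c in (set(channels) if channels else chans))
        if chans - set(self.channels):
            raise DpcrError("signature uses undeclared channels")
        self.class_counts = {
            signature_key(sig.split("+")) if sig != "NEG" else "NEG": int(n)
            for sig, n in class_counts.items()
        }
        if any(n < 0 for n in self.class_counts.values()):
            raise DpcrError("negative class count")
        total = sum(self.class_counts.values())
        if n_partitions is None:
            n_partitions = total
        elif n_partitions != total:
            raise DpcrError(f"class counts sum to {total}, not n_partitions={n_partitions}")
        self.n_partitions = n_partitions

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PartitionCounts":
        channels = [c for c in table.columns if c != "partition_id"]
        return cls(multiplex_classify(table), channels=channels)

    @classmethod
    def from_csv(cls, path: str) -> "PartitionCounts":
        df = pd.read_csv(path)
        if {"signature", "count"} <= set(df.columns):  # dialect B
            return cls(dict(zip(df["signature"].astype(str), df["count"].astype(int))))
        return cls.from_table(df)

    def to_csv(self, path: str) -> None:
        rows = sorted(self.class_counts.items())
        pd.DataFrame(rows, columns=["signature", "count"]).to_csv(path, index=False)

    def matching(self, include=(), exclude=()) -> int:
        """Partitions positive for every ``include`` channel and negative
        for every ``exclude`` channel."""
        inc, exc = set(include), set(exclude)
        total = 0
        for sig, n in self.class_counts.items():
            pos = set() if sig == "NEG" else set(sig.split("+"))
            if inc <= pos and not exc & pos:
                total += n
        return total

    def positive(self, channel: str) -> int:
        return self.matching(include=(channel,))

    def channel(self, channel: str) -> ChannelCount:
        return ChannelCount(self.positive(channel), self.n_partitions)


def merge_wells(wells: list[PartitionCounts]) -> PartitionCounts:
    """Sum class counts of replicate wells before estimation."""
    if not wells:
        raise DpcrError("no wells to merge")
    channels = wells[0].channels
    if any(w.channels != channels for w in wells):
        raise DpcrError("wells have differing channel sets")
    merged: dict[str, int] = {}
    for w in wells:
        for sig, n in w.class_counts.items():
            merged[sig] = merged.get(sig, 0) + n
    return PartitionCounts(merged, channels=channels)


def multiplex_excision_frequency(
    counts: PartitionCounts,
    edit_channel: str = "ROX",
    ref_channel: str = "CY5",
    mode: str = "raw",
) -> QuantResult:
    """Excision frequency from the 4-color assay: ROX+/CY5+ partition ratio
    (raw mode, the stated formula) or the Poisson-corrected equivalent."""
    edit = counts.channel(edit_channel)
    ref = counts.channel(ref_channel)
    if edit.n_positive == 0:
        return QuantResult(0.0, (0.0, 0.0), mode)
    r, se, lambdas = _ratio_with_se(edit, ref, mode)
    f = 100.0 * r
    return QuantResult(
        f, (max(0.0, f - Z95 * 100 * se), f + Z95 * 100 * se), mode, _lambda_values(lambdas)
    )


def multiplex_excision_specificity(
    counts: PartitionCounts,
    edit_channel: str = "ROX",
    target_channel: str = "FAM",
    nontarget_channel: str = "VIC",
    ref_channel: str = "CY5",
    mode: str = "raw",
) -> tuple[QuantResult, SpecificityResult]:
    """Combined excision frequency and allele specificity from 4-color data.

    Specificity = (edit+ and target-allele+ only) / (all edit+ partitions
    positive for exactly one allele probe).  Triple-positive partitions
    (edit + both alleles) are ambiguous, always excluded, and reported as
    a fraction of all edit-positive partitions (warning at >= 10%).
    """
    freq = multiplex_excision_frequency(counts, edit_channel, ref_channel, mode)
    target_only = counts.matching((edit_channel, target_channel), (nontarget_channel,))
    nontarget_only = counts.matching((edit_channel, nontarget_channel), (target_channel,))
    triple = counts.matching((edit_channel, target_channel, nontarget_channel))
    edit_pos = counts.positive(edit_channel)
    denom = target_only + nontarget_only
    if denom == 0:
        raise UndefinedSpecificityError(
            "no edit-positive partitions with an unambiguous allele signal"
        )
    spec = SpecificityResult(
        target_fraction=target_only / denom,
        excluded_triple_fraction=(triple / edit_pos) if edit_pos else 0.0,
        counts={
            "target_only": target_only,
            "nontarget_only": nontarget_only,
            "triple_positive": triple,
            "edit_positive": edit_pos,
        },
    )
    return freq, spec
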