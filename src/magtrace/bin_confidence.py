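"""Confidence statistics for pathway absence/presence in incomplete bins.

Two complementary questions about a draft genome bin recovered from a
metagenome:

1. *Absence*: given a bin of ``n`` coding sequences at estimated completeness
   ``completeness``, what is the probability that all ``r`` genes of a pathway
   are truly absent rather than merely unsampled?  Modelled as the
   hypergeometric probability of drawing zero pathway genes when ``n`` genes
   are sampled uniformly without replacement from an estimated total of
   ``T = round(n / completeness)`` genes.

2. *False assignment*: given estimated contamination ``C`` and ``k`` distinct
   contigs carrying the recovered pathway genes, the probability that every
   one of those contigs was mis-binned is ``P = C**k``.

All probabilities are evaluated exactly as rationals so that extreme tails
(down to 1e-13 and below) remain representable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from magtrace.errors import (
    DegenerateBinError,
    DomainError,
    InputError,
    InvalidQualityError,
)

DEFAULT_ABSENCE_THRESHOLD = 0.05


def as_fraction(value: float, what: str = "value") -> float:
    """Normalize a percent-or-fraction quantity to a fraction.

    Values in (1, 100] are interpreted as percentages and scaled down with a
    warning (the ambiguity is inherent to mixed input conventions); values
    above 100 are rejected.
    """
    if value < 0:
        raise InvalidQualityError(f"{what} must be non-negative, got {value}")
    if value > 100:
        raise InvalidQualityError(f"{what} above 100: {value}")
    if value > 1:
        warnings.warn(
            f"{what} {value} interpreted as percent and scaled to {value / 100}",
            stacklevel=3,
        )
        return value / 100.0
    return value


@dataclass(frozen=True)
class BinQuality:
    """Recovered gene count and quality estimates for one genome bin.

    ``completeness``, ``contamination`` and ``strain_heterogeneity`` are
    fractions; use :meth:`from_percent` for percent-scale inputs.
    """

    bin_id: str
    n_recovered: int
    completeness: float
    contamination: float = 0.0
    strain_heterogeneity: float = 0.0

    def __post_init__(self):
        if self.n_recovered < 0:
            raise InvalidQualityError(
                f"{self.bin_id}: n_recovered must be >= 0, got {self.n_recovered}"
            )
        if not (0 < self.completeness <= 1):
            raise InvalidQualityError(
                f"{self.bin_id}: completeness must be in (0, 1], got {self.completeness}"
            )
        if not (0 <= self.contamination < 1):
            raise InvalidQualityError(
                f"{self.bin_id}: contamination must be in [0, 1), got {self.contamination}"
            )
        if not (0 <= self.strain_heterogeneity <= 1):
            raise InvalidQualityError(
                f"{self.bin_id}: strain heterogeneity must be in [0, 1], "
                f"got {self.strain_heterogeneity}"
            )

    @classmethod
    def from_percent(
        cls,
        bin_id: str,
        n_recovered: int,
        completeness_pct: float,
        contamination_pct: float = 0.0,
        strain_het_pct: float = 0.0,
    ) -> "BinQuality":
        return cls(
            bin_id=bin_id,
            n_recovered=n_recovered,
            completeness=completeness_pct / 100.0,
            contamination=contamination_pct / 100.0,
            strain_heterogeneity=strain_het_pct / 100.0,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named pathway/marker set; ``size`` is the number of member genes."""

    set_id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) < 1:
            raise InputError(f"gene set {self.set_id} is empty")
        if len(set(self.members)) != len(self.members):
            raise InputError(f"gene set {self.set_id} has duplicate members")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AbsenceResult:
    bin_id: str
    gene_set_id: str
    total_genes: int
    prob_zero_recovered: float
    flag_inconclusive: bool
    threshold: float = DEFAULT_ABSENCE_THRESHOLD


@dataclass(frozen=True)
class FalseAssignmentResult:
    bin_id: str
    k_contigs: int
    prob_all_contaminant: float
    prob_all_contaminant_adjusted: float
    gene_set_id: str | None = None


def estimate_total_genes(n_recovered: int, completeness: float) -> int:
    """Estimate total genome gene count as ``round(n / completeness)``.

    Uses banker's rounding (round-half-to-even); results are insensitive to
    the rounding convention at the precision of any reported probability.
    """
    if n_recovered == 0:
        raise DegenerateBinError("bin has no recovered coding sequences")
    if n_recovered < 0:
        raise DomainError(f"n_recovered must be positive, got {n_recovered}")
    if not (0 < completeness <= 1):
        raise InvalidQualityError(
            f"completeness must be in (0, 1], got {completeness}"
        )
    return max(n_recovered, round(n_recovered / completeness))


def hypergeom_pmf(T: int, n: int, r: int, x: int) -> float:
    """Exact hypergeometric pmf: probability that exactly ``x`` of the ``r``
    pathway genes fall among the ``n`` recovered out of ``T`` total.

    Evaluated as an exact rational C(n,x)*C(T-n,r-x)/C(T,r) before conversion
    to float, so tail values far below double rounding error of naive products
    are exact to the last ulp.
    """
    for name, v in (("T", T), ("n", n), ("r", r), ("x", x)):
        if v < 0:
            raise DomainError(f"{name} must be non-negative, got {v}")
    if n > T:
        raise DomainError(f"n ({n}) exceeds T ({T})")
    if r > T:
        raise DomainError(f"r ({r}) exceeds T ({T})")
    if r < 1:
        raise DomainError("r must be >= 1")
    if x > min(r, n):
        raise DomainError(f"x ({x}) exceeds min(r, n) = {min(r, n)}")
    if r - x > T - n:
        return 0.0
    num = math.comb(n, x) * math.comb(T - n, r - x)
    return float(Fraction(num, math.comb(T, r)))


def prob_absent(
    bin: BinQuality,
    gene_set: GeneSet,
    threshold: float = DEFAULT_ABSENCE_THRESHOLD,
) -> AbsenceResult:
    """Probability that zero genes of ``gene_set`` were recovered by chance.

    A result above ``threshold`` is flagged inconclusive: the bin is too
    incomplete to call the pathway absent.
    """
    T = estimate_total_genes(bin.n_recovered, bin.completeness)
    r = min(gene_set.size, T)  # r cannot exceed the genome
    p = hypergeom_pmf(T, bin.n_recovered, r, 0)
    return AbsenceResult(
        bin_id=bin.bin_id,
        gene_set_id=gene_set.set_id,
        total_genes=T,
        prob_zero_recovered=p,
        flag_inconclusive=p > threshold,
        threshold=threshold,
    )


def prob_false_assignment(
    bin: BinQuality, k_contigs: int, gene_set_id: str | None = None
) -> FalseAssignmentResult:
    """Probability that all ``k_contigs`` supporting contigs are contaminants.

    ``P = C**k`` with C the contamination fraction.  The adjusted variant
    discounts the strain-heterogeneity share of C (contamination from close
    strains is not evidence of mis-assignment to the wrong organism):
    ``P_adj = (C * (1 - strain_heterogeneity))**k``.
    """
    if k_contigs < 0:
        raise DomainError(f"k_contigs must be >= 0, got {k_contigs}")
    c = bin.contamination
    c_adj = c * (1.0 - bin.strain_heterogeneity)
    return FalseAssignmentResult(
        bin_id=bin.bin_id,
        k_contigs=k_contigs,
        prob_all_contaminant=c**k_contigs,
        prob_all_contaminant_adjusted=c_adj**k_contigs,
        gene_set_id=gene_set_id,
    )


def absence_report(
    bins: Sequence[BinQuality],
    gene_sets: Sequence[GeneSet],
    threshold: float = DEFAULT_ABSENCE_THRESHOLD,
) -> pd.DataFrame:
    """Batch absence probabilities: one row per (bin, gene set), sorted."""
    if not bins:
        raise InputError("no bins supplied")
    if not gene_sets:
        raise InputError("no gene sets supplied")
    ids = [b.bin_id for b in bins]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate bin_ids: {', '.join(dupes)}")
    set_ids = [g.set_id for g in gene_sets]
    if len(set(set_ids)) != len(set_ids):
        raise InputError("duplicate gene set ids")
    rows = []
    for b in bins:
        for g in gene_sets:
            res = prob_absent(b, g, threshold=threshold)
            rows.append(
                {
                    "bin_id": res.bin_id,
                    "gene_set_id": res.gene_set_id,
                    "n_recovered": b.n_recovered,
                    "completeness": b.completeness,
                    "total_genes": res.total_genes,
                    "prob_zero_recovered": res.prob_zero_recovered,
                    "flag_inconclusive": res.flag_inconclusive,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["bin_id", "gene_set_id"], kind="mergesort").reset_index(
        drop=True
    )


def read_bin_quality_tsv(path) -> list[BinQuality]:
    """Read a bin-quality table (percent-scale columns).

    Expected header: bin_id, n_cds, completeness_pct, contamination_pct,
    strain_het_pct.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "bin_id",
        "n_cds",
        "completeness_pct",
        "contamination_pct",
        "strain_het_pct",
    }
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"bin quality table missing columns: {sorted(missing)}")
    if df.empty:
        raise InputError("bin quality table has no rows")
    return [
        BinQuality.from_percent(
            str(row.bin_id),
            int(row.n_cds),
            float(row.completeness_pct),
            float(row.contamination_pct),
            float(row.strain_het_pct),
        )
        for row in df.itertuples()
    ]


def read_gene_sets_tsv(path) -> list[GeneSet]:
    """Read gene sets from a two-column TSV (set_id, gene_name)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"set_id", "gene_name"} <= set(df.columns):
        raise InputError("gene set table needs columns set_id, gene_name")
    sets = []
    for set_id, sub in df.groupby("set_id", sort=True):
        sets.append(GeneSet(set_id=str(set_id), members=tuple(sub["gene_name"])))
    if not sets:
        raise InputError("gene set table has no rows")
    return sets


def format_probability(p: float) -> str:
    """Scientific notation with 6 significant digits."""
    return f"{p:.6e}"


def write_absence_report(df: pd.DataFrame, tsv_path, json_path, header_lines=()):
    out = df.copy()
    out["prob_zero_recovered"] = out["prob_zero_recovered"].map(format_probability)
    with open(tsv_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)
    payload = {
        "meta": dict(kv.split("=", 1) for kv in header_lines if "=" in kv),
        "results": df.to_dict(orient="records"),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
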