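"""Segregation-distortion testing stratified by gene-conversion regions.

Pseudo-testcross SNPs segregate 1:1 (aa:ab) in the progeny under Mendelian
expectation; a chi-squared goodness-of-fit test against 1:1 flags distorted
SNPs (p < 0.01 by default).  SNPs are then stratified by whether they fall
inside genomic regions covered by gene-conversion tracts detected in at
least one progeny (GC) or at least five distinct progeny (GC5, a subset of
GC), and the distorted fraction is compared across strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

SEGREGATION_TYPES = ("abxaa", "aaxab")
REGIONS = ("Non-GC", "GC", "GC5")


@dataclass
class SegregationRecord:
    """Genotype counts of one pseudo-testcross SNP over a population."""

    chrom: str
    pos: int
    segregation_type: str  # "abxaa" or "aaxab"
    n_aa: int
    n_ab: int
    chi_sq: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def n_typed(self) -> int:
        return self.n_aa + self.n_ab

    def test(self) -> "SegregationRecord":
        self.chi_sq, self.p_value = chi_square_1to1(self.n_aa, self.n_ab)
        return self


def chi_square_1to1(n_aa: int, n_ab: int) -> tuple[float, float]:
    """Chi-squared goodness-of-fit test of counts against a 1:1 ratio.

    With n = (n_aa + n_ab)/2, the statistic is
    (n_aa - n)^2/n + (n_ab - n)^2/n on 1 degree of freedom; no continuity
    correction is applied.

    >>> chi_square_1to1(150, 150)
    (0.0, 1.0)
    """
    if n_aa < 0 or n_ab < 0:
        raise ValueError("counts must be non-negative")
    total = n_aa + n_ab
    if total == 0:
        raise ValueError("chi-squared test undefined for zero total count")
    n = total / 2.0
    stat = (n_aa - n) ** 2 / n + (n_ab - n) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


class GcRegionSet:
    """Genomic intervals with per-base distinct-progeny GC multiplicity.

    Built from gene-conversion tracts; the multiplicity of a base is the
    number of distinct progeny carrying a tract that covers it (multiple
    tracts from one progeny count once).  Coordinates are 1-based
    inclusive.
    """

    def __init__(self, intervals: Mapping[str, list[tuple[int, int, int]]]):
        # {chrom: [(start, end, multiplicity), ...]} non-overlapping, sorted
        self._intervals = {c: sorted(v) for c, v in intervals.items()}
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in self._intervals.items():
            tree = IntervalTree()
            for start, end, mult in ivs:
                if mult > 0:
                    tree[start : end + 1] = mult  # half-open internally
            self._trees[chrom] = tree

    def intervals(self, chrom: str) -> list[tuple[int, int, int]]:
        return list(self._intervals.get(chrom, []))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._intervals)

    def multiplicity(self, chrom: str, pos: int) -> int:
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        hits = tree[pos]
        return max((iv.data for iv in hits), default=0)


def build_gc_region_multiset(events: Iterable) -> GcRegionSet:
    """Reduce gene-conversion tracts to a per-base progeny-multiplicity map.

    Accepts any records with chrom, start, end (1-based inclusive),
    progeny_id and an ``event_class`` of ``gene_conversion`` (records of
    other classes are ignored).  Overlapping tracts from the same progeny
    are flattened before counting, so multiplicity is the number of
    distinct progeny covering each base.
    """
    per_progeny: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ev in events:
        if getattr(ev, "event_class", "gene_conversion") != "gene_conversion":
            continue
        per_progeny.setdefault(ev.chrom, {}).setdefault(ev.progeny_id, []).append(
            (ev.start, ev.end)
        )

    intervals: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, by_progeny in per_progeny.items():
        # breakpoint sweep over per-progeny flattened tracts
        deltas: dict[int, int] = {}
        for tracts in by_progeny.values():
            for start, end in _flatten(tracts):
                deltas[start] = deltas.get(start, 0) + 1
                deltas[end + 1] = deltas.get(end + 1, 0) - 1
        out: list[tuple[int, int, int]] = []
        level = 0
        points = sorted(deltas)
        for left, right in zip(points, points[1:]):
            level += deltas[left]
            if level > 0:
                out.append((left, right - 1, level))
        intervals[chrom] = _coalesce(out)
    return GcRegionSet(intervals)


def _flatten(tracts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(tracts):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _coalesce(ivs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    out: list[list[int]] = []
    for start, end, mult in ivs:
        if out and out[-1][2] == mult and start == out[-1][1] + 1:
            out[-1][1] = end
        else:
            out.append([start, end, mult])
    return [tuple(iv) for iv in out]


def classify_snp_region(
    chrom: str, pos: int, region_set: GcRegionSet, gc5_min: int = 5
) -> str:
    """Region membership of one base: GC5 (>=5 progeny), GC (>=1), Non-GC."""
    mult = region_set.multiplicity(chrom, pos)
    if mult >= gc5_min:
        return "GC5"
    if mult >= 1:
        return "GC"
    return "Non-GC"


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding used for reported percentages."""
    return float(np.round(x, ndigits))


def percent_distorted(n_snps: int, n_distorted: int) -> float:
    """Distorted percentage as reported: 100 * distorted / total, 2 decimals."""
    if n_snps == 0:
        return float("nan")
    return round_half_even(100.0 * n_distorted / n_snps, 2)


def summarize_region_counts(counts: Mapping[tuple[str, str], tuple[int, int]]) -> pd.DataFrame:
    """Shape (segregation type, region) -> (n_snps, n_distorted) into a report.

    This is the reporting path shared by :func:`distortion_summary`; it can
    also be fed externally tabulated counts.  Percentages are
    100 * distorted / total rounded half-even to two decimals; empty
    regions render as NaN.
    """
    rows = []
    for seg in SEGREGATION_TYPES:
        for region in REGIONS:
            n_snps, n_dist = counts.get((seg, region), (0, 0))
            rows.append(
                {
                    "segregation_type": seg,
                    "region": region,
                    "n_snps": n_snps,
                    "n_distorted": n_dist,
                    "percent": percent_distorted(n_snps, n_dist),
                }
            )
    return pd.DataFrame(rows)


def distortion_summary(
    records: Sequence[SegregationRecord],
    region_set: GcRegionSet,
    min_typed: int = 100,
    alpha: float = 0.01,
    gc5_min: int = 5,
) -> dict:
    """Distorted-SNP rates by segregation type and GC-region stratum.

    Records with fewer than ``min_typed`` genotyped progeny are dropped.
    A record is distorted when its 1:1 chi-squared p-value is below
    ``alpha``.  The ``nested`` table counts GC as multiplicity >= 1
    (GC5 is a subset of GC, as reported); the ``exclusive`` table makes
    the three regions a partition (GC row restricted to multiplicity in
    [1, gc5_min)).
    """
    nested: dict[tuple[str, str], list[int]] = {}
    exclusive: dict[tuple[str, str], list[int]] = {}
    per_snp = []
    for rec in records:
        if rec.n_typed < min_typed:
            continue
        if rec.p_value is None:
            rec.test()
        distorted = rec.p_value < alpha
        mult = region_set.multiplicity(rec.chrom, rec.pos)
        region = "GC5" if mult >= gc5_min else ("GC" if mult >= 1 else "Non-GC")
        per_snp.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "segregation_type": rec.segregation_type,
                "n_aa": rec.n_aa,
                "n_ab": rec.n_ab,
                "chi_sq": rec.chi_sq,
                "p_value": rec.p_value,
                "distorted": distorted,
                "multiplicity": mult,
                "region": region,
            }
        )
        for table, reg in (
            (exclusive, region),
            (nested, "Non-GC" if region == "Non-GC" else "GC"),
        ):
            cell = table.setdefault((rec.segregation_type, reg), [0, 0])
            cell[0] += 1
            cell[1] += int(distorted)
        if region == "GC5":  # nested: GC5 sites also count in the GC row
            cell = nested.setdefault((rec.segregation_type, "GC5"), [0, 0])
            cell[0] += 1
            cell[1] += int(distorted)

    return {
        "nested": summarize_region_counts(
            {k: tuple(v) for k, v in nested.items()}
        ),
        "exclusive": summarize_region_counts(
            {k: tuple(v) for k, v in exclusive.items()}
        ),
        "per_snp": pd.DataFrame(per_snp),
    }


def read_population_matrix(path) -> list[SegregationRecord]:
    """Read a population genotype matrix TSV into segregation records.

    Columns: chrom, pos, segregation_type, then one column per progeny
    with genotypes in {aa, ab, --} ('--' = untyped, excluded from counts).
    """
    import csv

    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fixed = {"chrom", "pos", "segregation_type"}
        missing = fixed - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"population matrix missing column(s): {sorted(missing)}")
        progeny_cols = [c for c in reader.fieldnames if c not in fixed]
        for row in reader:
            genos = [row[c] for c in progeny_cols]
            records.append(
                SegregationRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    segregation_type=row["segregation_type"],
                    n_aa=sum(g == "aa" for g in genos),
                    n_ab=sum(g == "ab" for g in genos),
                )
            )
    return records
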