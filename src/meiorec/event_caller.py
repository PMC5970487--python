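"""Recombination-event calling from progeny genotypes over parental blocks.

At pseudo-testcross sites the homozygous parent can only transmit the 'a'
allele, so a progeny genotyped 'aa' inherited 'a' from the focal
(heterozygous) parent and a progeny genotyped 'ab' inherited 'b'.  The
resulting per-site label sequence is matched against the focal parent's
two homolog label strings, segmented into maximal runs of constant
homolog, and the runs are classified:

- an interior run (flanked on both sides by the opposite homolog) whose
  SNP span is at least 20 bp and under 2 kb and that carries at least two
  SNPs is a gene-conversion tract;
- a junction between two adjacent runs each spanning more than 10 kb is a
  crossover, localized to the interval between the flanking SNPs;
- interior runs spanning under 20 bp or carrying a single SNP are ignored
  (too short to call);
- every other interior run (2 kb up to and beyond 10 kb) is ambiguous —
  too long for a conversion tract, not flanked well enough for a
  crossover.

Tract length is measured as the span from the first to the last SNP of
the run, inclusive.  Missing sites never terminate a run: continuity is
judged on informative sites only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from meiorec.formats_io import VcfSiteCall
from meiorec.parent_blocks import HaplotypeBlock

logger = logging.getLogger(__name__)

LENGTH_BINS: list[tuple[float, float, str]] = [
    (2, 20, "2-19 bp"),
    (20, 200, "20-200 bp"),
    (200, 1000, "200 bp-1 kb"),
    (1000, 2000, "1-2 kb"),
    (2000, 10000, "2-10 kb"),
    (10000, math.inf, ">=10 kb"),
]
BIN_LABELS = [label for _, _, label in LENGTH_BINS]


@dataclass
class ProgenyHaplotype:
    """Per-site labels a progeny inherited from the focal parent."""

    progeny_id: str
    parent_of_origin: str
    block: HaplotypeBlock
    calls: list[str]  # per block site, in {"a", "b", "missing"}
    n_incompatible: int = 0  # 'bb' genotypes at ab x aa sites

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.block.sites):
            raise ValueError("calls must align with block sites")


@dataclass(frozen=True)
class Run:
    """A maximal run of sites inherited from one parental homolog."""

    homolog: int  # 1 or 2
    first_site_idx: int
    last_site_idx: int
    span_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.span_bp < 1:
            raise ValueError("degenerate run")


@dataclass(frozen=True)
class RecombinationEvent:
    """A classified fragment or crossover junction in one progeny."""

    progeny_id: str
    parent_of_origin: str
    chrom: str
    event_class: str  # gene_conversion | crossover | ignored_short | ambiguous
    start: int  # 1-based inclusive; for crossover: last SNP of the left run
    end: int  # 1-based inclusive; for crossover: first SNP of the right run
    n_snps: int
    source_block: str = ""
    outer_start: Optional[int] = None  # flanking opposite-state SNP positions
    outer_end: Optional[int] = None

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def filter_progeny_genotype(
    call: VcfSiteCall,
    min_depth: int = 15,
    min_gq: float = 60,
    min_allele_reads: int = 5,
) -> bool:
    """Progeny genotype quality gate.

    Requires depth of at least ``min_depth`` reads, genotype quality
    strictly greater than ``min_gq``, and at least ``min_allele_reads``
    reads on each called allele (both alleles for a heterozygote, the
    single allele for a homozygote).
    """
    if call.genotype == "missing":
        return False
    if call.depth < min_depth:
        return False
    if not call.genotype_quality > min_gq:
        return False
    if call.genotype == "het":
        return min(call.allele_depths) >= min_allele_reads
    idx = 0 if call.genotype == "hom_ref" else 1
    return call.allele_depths[idx] >= min_allele_reads


def infer_inherited_haplotype(
    progeny_calls: Mapping[tuple[str, int], VcfSiteCall],
    block: HaplotypeBlock,
    progeny_id: str = "progeny",
    min_depth: int = 15,
    min_gq: float = 60,
    min_allele_reads: int = 5,
) -> ProgenyHaplotype:
    """Infer which focal-parent allele the progeny inherited at each site.

    Genotype 'aa' implies label 'a', 'ab' implies 'b' (the other parent
    can only transmit 'a').  A 'bb' genotype is Mendelian-impossible at a
    pseudo-testcross site; it is recorded as missing and counted in
    ``n_incompatible``.  Sites failing :func:`filter_progeny_genotype`,
    absent from the progeny's calls, or carrying alleles unknown to the
    parental site are missing.
    """
    labels: list[str] = []
    n_incompatible = 0
    for site in block.sites:
        call = progeny_calls.get((site.chrom, site.pos))
        if call is None or not filter_progeny_genotype(
            call, min_depth=min_depth, min_gq=min_gq, min_allele_reads=min_allele_reads
        ):
            labels.append("missing")
            continue
        if call.genotype == "hom_ref":
            obs = (call.ref_allele, call.ref_allele)
        elif call.genotype == "hom_alt":
            obs = (call.alt_allele, call.alt_allele)
        else:
            obs = (call.ref_allele, call.alt_allele)
        ab = tuple(site.label_of_allele(x) for x in obs)
        if None in ab:
            logger.debug(
                "%s:%d progeny allele outside parental alleles", site.chrom, site.pos
            )
            labels.append("missing")
            continue
        n_b = ab.count("b")
        if n_b == 0:
            labels.append("a")
        elif n_b == 1:
            labels.append("b")
        else:
            n_incompatible += 1
            labels.append("missing")
    return ProgenyHaplotype(
        progeny_id=progeny_id,
        parent_of_origin=block.parent_id,
        block=block,
        calls=labels,
        n_incompatible=n_incompatible,
    )


def segment_runs(
    prog_hap: ProgenyHaplotype,
    parent_block: Optional[HaplotypeBlock] = None,
    max_gap_bp: Optional[int] = None,
) -> list[Run]:
    """Segment the inherited labels into maximal same-homolog runs.

    Each informative site is assigned to the parental homolog whose a/b
    label matches the inherited label.  Missing sites never break a run
    unless ``max_gap_bp`` is set and the gap between consecutive
    informative sites exceeds it.
    """
    block = parent_block if parent_block is not None else prog_hap.block
    informative: list[tuple[int, int]] = []  # (site index, homolog)
    for idx, label in enumerate(prog_hap.calls):
        if label == "missing":
            continue
        site = block.sites[idx]
        if label == site.ab_label_hap1:
            hom = 1
        elif label == site.ab_label_hap2:
            hom = 2
        else:  # impossible by construction: labels partition {a, b}
            raise AssertionError(
                f"label {label!r} matches neither homolog at {site.chrom}:{site.pos}"
            )
        informative.append((idx, hom))
    return segment_assignments(informative, block, max_gap_bp=max_gap_bp)


def segment_assignments(
    assignments: Sequence[tuple[int, int]],
    block: HaplotypeBlock,
    max_gap_bp: Optional[int] = None,
) -> list[Run]:
    """Maximal same-homolog runs from explicit (site index, homolog) pairs.

    The core of :func:`segment_runs`, also usable with externally derived
    homolog assignments (e.g. simulator ground truth at the same sites).
    """
    runs: list[Run] = []
    for idx, hom in assignments:
        pos = block.sites[idx].pos
        if runs:
            prev = runs[-1]
            prev_pos = block.sites[prev.last_site_idx].pos
            gap_ok = max_gap_bp is None or pos - prev_pos <= max_gap_bp
            if prev.homolog == hom and gap_ok:
                runs[-1] = Run(
                    homolog=hom,
                    first_site_idx=prev.first_site_idx,
                    last_site_idx=idx,
                    span_bp=pos - block.sites[prev.first_site_idx].pos + 1,
                    n_snps=prev.n_snps + 1,
                )
                continue
        runs.append(
            Run(homolog=hom, first_site_idx=idx, last_site_idx=idx, span_bp=1, n_snps=1)
        )
    return runs


def classify_fragments(
    runs: Sequence[Run],
    block: HaplotypeBlock,
    progeny_id: str = "progeny",
    gc_min_bp: int = 20,
    gc_max_bp: int = 2000,
    co_flank_bp: int = 10000,
    gc_min_snps: int = 2,
) -> list[RecombinationEvent]:
    """Classify homolog runs into recombination events.

    Every interior run receives exactly one class (gene_conversion,
    ignored_short or ambiguous); every junction between two adjacent runs
    both spanning more than ``co_flank_bp`` additionally yields a
    crossover event.  Terminal runs generate no fragment call.
    """
    events: list[RecombinationEvent] = []

    def pos(i: int) -> int:
        return block.sites[i].pos

    for k, run in enumerate(runs):
        if k == 0 or k == len(runs) - 1:
            continue  # terminal runs: no opposite-homolog flank on both sides
        if run.span_bp < gc_min_bp or run.n_snps < gc_min_snps:
            cls = "ignored_short"
        elif run.span_bp < gc_max_bp:
            cls = "gene_conversion"
        else:
            cls = "ambiguous"
        events.append(
            RecombinationEvent(
                progeny_id=progeny_id,
                parent_of_origin=block.parent_id,
                chrom=block.chrom,
                event_class=cls,
                start=pos(run.first_site_idx),
                end=pos(run.last_site_idx),
                n_snps=run.n_snps,
                source_block=block.block_id,
                outer_start=pos(runs[k - 1].last_site_idx),
                outer_end=pos(runs[k + 1].first_site_idx),
            )
        )

    for left, right in zip(runs, runs[1:]):
        if left.span_bp > co_flank_bp and right.span_bp > co_flank_bp:
            events.append(
                RecombinationEvent(
                    progeny_id=progeny_id,
                    parent_of_origin=block.parent_id,
                    chrom=block.chrom,
                    event_class="crossover",
                    start=pos(left.last_site_idx),
                    end=pos(right.first_site_idx),
                    n_snps=0,
                    source_block=block.block_id,
                )
            )
    return events


def call_events_for_block(
    block: HaplotypeBlock,
    progeny_calls: Mapping[tuple[str, int], VcfSiteCall],
    progeny_id: str = "progeny",
    min_depth: int = 15,
    min_gq: float = 60,
    min_allele_reads: int = 5,
    gc_min_bp: int = 20,
    gc_max_bp: int = 2000,
    co_flank_bp: int = 10000,
    gc_min_snps: int = 2,
    max_gap_bp: Optional[int] = None,
) -> tuple[list[RecombinationEvent], ProgenyHaplotype]:
    """Convenience chain: infer labels, segment runs, classify events."""
    prog_hap = infer_inherited_haplotype(
        progeny_calls,
        block,
        progeny_id=progeny_id,
        min_depth=min_depth,
        min_gq=min_gq,
        min_allele_reads=min_allele_reads,
    )
    runs = segment_runs(prog_hap, max_gap_bp=max_gap_bp)
    events = classify_fragments(
        runs,
        block,
        progeny_id=progeny_id,
        gc_min_bp=gc_min_bp,
        gc_max_bp=gc_max_bp,
        co_flank_bp=co_flank_bp,
        gc_min_snps=gc_min_snps,
    )
    return events, prog_hap


def bin_events_by_length(events: Iterable[RecombinationEvent]) -> pd.DataFrame:
    """Histogram fragment events per chromosome over the standard length bins.

    Bins are closed-open on the listed left edges: [2,20), [20,200),
    [200,1000), [1000,2000), [2000,10000), [10000,inf).  Crossover
    junctions carry no fragment length and are not binned.
    """
    counts: dict[str, list[int]] = {}
    for ev in events:
        if ev.event_class == "crossover":
            continue
        row = counts.setdefault(ev.chrom, [0] * len(LENGTH_BINS))
        for j, (lo, hi, _) in enumerate(LENGTH_BINS):
            if lo <= ev.span_bp < hi:
                row[j] += 1
                break
    df = pd.DataFrame.from_dict(counts, orient="index", columns=BIN_LABELS)
    df = df.sort_index()
    df.index.name = "chrom"
    if len(df):
        df.loc["Total"] = df.sum()
    return df


def summarize_per_progeny(
    events: Iterable[RecombinationEvent],
    progeny_ids: Optional[Sequence[str]] = None,
) -> dict:
    """Per-chromosome GC counts by progeny, averages, and block sharing.

    Returns a dict with:

    - ``per_chrom``: DataFrame of gene-conversion counts (rows =
      chromosomes plus Total, columns = progeny plus ``Aver.``, the
      arithmetic mean over progeny);
    - ``block_sharing``: Series indexed 1..n of the number of source
      blocks in which gene conversions were detected in exactly k progeny.
    """
    events = [ev for ev in events if ev.event_class == "gene_conversion"]
    if progeny_ids is None:
        progeny_ids = sorted({ev.progeny_id for ev in events})
    progeny_ids = list(progeny_ids)

    chroms = sorted({ev.chrom for ev in events})
    counts = pd.DataFrame(0, index=chroms, columns=progeny_ids, dtype=int)
    block_progeny: dict[str, set[str]] = {}
    for ev in events:
        counts.loc[ev.chrom, ev.progeny_id] += 1
        block_progeny.setdefault(ev.source_block, set()).add(ev.progeny_id)

    table = counts.copy().astype(float)
    table["Aver."] = counts.mean(axis=1) if progeny_ids else 0.0
    if len(table):
        table.loc["Total"] = table.sum()
    table.index.name = "chrom"

    n = len(progeny_ids)
    sharing = pd.Series(0, index=range(1, n + 1), dtype=int, name="n_blocks")
    for members in block_progeny.values():
        k = len(members)
        if 1 <= k <= n:
            sharing[k] += 1
    sharing.index.name = "n_progeny"
    return {"per_chrom": table, "block_sharing": sharing}
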