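"""End-to-end in-memory analysis: blocks -> merge -> events.

Gene-conversion tracts are called within the short phased blocks (the
paper-scale unit where tracts fit between opposite-homolog flanks), while
crossovers are taken from the merged chromosome-scale haplotypes, plus
from short blocks that could not join a merged haplotype (a block can
occasionally span more than the crossover flank threshold on its own).
This split avoids double-counting events present in both views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from meiorec.event_caller import (
    RecombinationEvent,
    classify_fragments,
    infer_inherited_haplotype,
    segment_assignments,
    segment_runs,
)
from meiorec.formats_io import VcfSiteCall
from meiorec.parent_blocks import (
    ChromosomeHaplotype,
    HaplotypeBlock,
    assign_ab_labels,
    build_parent_blocks,
    merge_blocks_with_map,
)
from meiorec.simulate import SimulatedDataset


@dataclass(frozen=True)
class CallerParams:
    """All tunable thresholds of the detection pipeline."""

    min_block_snps: int = 5
    parent_min_depth: int = 5
    parent_min_allele_reads: int = 3
    parent_min_gq: float = 60
    progeny_min_depth: int = 15
    progeny_min_gq: float = 60
    progeny_min_allele_reads: int = 5
    gc_min_bp: int = 20
    gc_max_bp: int = 2000
    co_flank_bp: int = 10000
    gc_min_snps: int = 2
    max_gap_bp: Optional[int] = None


@dataclass
class AnalysisResult:
    """Pipeline products for one dataset."""

    params: CallerParams
    blocks: dict[str, list[HaplotypeBlock]]
    merged: dict[str, dict[str, ChromosomeHaplotype]]
    events: list[RecombinationEvent]
    expected_events: list[RecombinationEvent] = field(default_factory=list)
    informative_sites: dict[tuple[str, str, str], list[int]] = field(
        default_factory=dict
    )
    pt_site_positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)


def build_labelled_blocks(
    phased_groups: Mapping,
    other_parent_calls: Mapping[tuple[str, int], VcfSiteCall],
    parent_id: str,
    params: CallerParams = CallerParams(),
) -> list[HaplotypeBlock]:
    """Filter phase sets into blocks and assign a/b labels.

    Blocks that drop below the minimum SNP count after label
    assignment (tri-allelic inconsistencies) are discarded, mirroring
    the construction filter.
    """
    blocks = build_parent_blocks(
        phased_groups,
        other_parent_calls,
        parent_id=parent_id,
        min_snps=params.min_block_snps,
        min_depth=params.parent_min_depth,
        min_allele_reads=params.parent_min_allele_reads,
        min_gq=params.parent_min_gq,
    )
    labelled = []
    for blk in blocks:
        lab = assign_ab_labels(blk, other_parent_calls)
        if lab.n_sites >= params.min_block_snps:
            labelled.append(lab)
    return labelled


def _call_unit(
    unit: HaplotypeBlock,
    progeny_calls: Mapping[tuple[str, int], VcfSiteCall],
    progeny_id: str,
    params: CallerParams,
    keep: tuple[str, ...],
) -> tuple[list[RecombinationEvent], list[int]]:
    prog_hap = infer_inherited_haplotype(
        progeny_calls,
        unit,
        progeny_id=progeny_id,
        min_depth=params.progeny_min_depth,
        min_gq=params.progeny_min_gq,
        min_allele_reads=params.progeny_min_allele_reads,
    )
    runs = segment_runs(prog_hap, max_gap_bp=params.max_gap_bp)
    events = classify_fragments(
        runs,
        unit,
        progeny_id=progeny_id,
        gc_min_bp=params.gc_min_bp,
        gc_max_bp=params.gc_max_bp,
        co_flank_bp=params.co_flank_bp,
        gc_min_snps=params.gc_min_snps,
    )
    informative_idx = [
        i for i, lab in enumerate(prog_hap.calls) if lab != "missing"
    ]
    return [ev for ev in events if ev.event_class in keep], informative_idx


def _co_from_short_block(blk: HaplotypeBlock, merged_haps) -> bool:
    """Whether a short block may contribute crossover junctions.

    Only blocks outside every merged haplotype's physical span qualify;
    junctions inside a merged span are already visible to the merged
    unit, and calling them twice would double-count.
    """
    for ch in merged_haps:
        if ch.block.chrom != blk.chrom or not ch.block.sites:
            continue
        if blk.span_start >= ch.block.span_start and blk.span_end <= ch.block.span_end:
            return False
    return True


def analyze_dataset(
    ds: SimulatedDataset,
    params: CallerParams = CallerParams(),
    with_expected: bool = True,
) -> AnalysisResult:
    """Run the full caller on a simulated dataset.

    When ``with_expected`` is set, the classifier is additionally applied
    to the TRUE inherited homolog (from the simulator's gamete records) at
    exactly the informative sites the pipeline used; the resulting
    ``expected_events`` define which truth events were in principle
    callable and feed :func:`meiorec.simulate.recovery_compare`.
    """
    fragment_classes = ("gene_conversion", "ignored_short", "ambiguous")
    blocks: dict[str, list[HaplotypeBlock]] = {}
    merged: dict[str, dict[str, ChromosomeHaplotype]] = {}
    events: list[RecombinationEvent] = []
    expected: list[RecombinationEvent] = []
    informative_sites: dict[tuple[str, str, str], set[int]] = {}
    pt_positions: dict[tuple[str, str], list[int]] = {}

    pos_index = {
        chrom.name: {int(p): i for i, p in enumerate(chrom.positions)}
        for chrom in ds.parents.chroms
    }
    for chrom in ds.parents.chroms:
        for parent in ("P1", "P2"):
            pt_positions[(parent, chrom.name)] = [
                int(p) for p in chrom.positions[chrom.pt_mask(parent)]
            ]

    for parent in ("P1", "P2"):
        other = "P2" if parent == "P1" else "P1"
        blks = build_labelled_blocks(
            ds.parents.phased_groups[parent],
            ds.parents.calls[other],
            parent_id=parent,
            params=params,
        )
        blocks[parent] = blks
        merged_here = merge_blocks_with_map(blks, ds.parents.linkage_maps[parent])
        merged[parent] = merged_here
        units: list[tuple[HaplotypeBlock, tuple[str, ...]]] = []
        for blk in blks:
            keep = fragment_classes
            if _co_from_short_block(blk, merged_here.values()):
                keep = keep + ("crossover",)
            units.append((blk, keep))
        for ch in merged_here.values():
            units.append((ch.block, ("crossover",)))

        for pid in ds.progeny_ids:
            calls = ds.progeny_calls[pid]
            for unit, keep in units:
                unit_events, informative_idx = _call_unit(
                    unit, calls, pid, params, keep
                )
                events.extend(unit_events)
                key = (pid, parent, unit.chrom)
                informative_sites.setdefault(key, set()).update(
                    unit.sites[i].pos for i in informative_idx
                )
                if with_expected:
                    hom = ds.gamete_homologs[(pid, parent, unit.chrom)]
                    idx_of = pos_index[unit.chrom]
                    assignments = [
                        (i, int(hom[idx_of[unit.sites[i].pos]]) + 1)
                        for i in informative_idx
                    ]
                    runs = segment_assignments(assignments, unit)
                    exp = classify_fragments(
                        runs,
                        unit,
                        progeny_id=pid,
                        gc_min_bp=params.gc_min_bp,
                        gc_max_bp=params.gc_max_bp,
                        co_flank_bp=params.co_flank_bp,
                        gc_min_snps=params.gc_min_snps,
                    )
                    expected.extend(ev for ev in exp if ev.event_class in keep)

    return AnalysisResult(
        params=params,
        blocks=blocks,
        merged=merged,
        events=events,
        expected_events=expected,
        informative_sites={
            k: sorted(v) for k, v in informative_sites.items()
        },
        pt_site_positions=pt_positions,
    )


def call_events_population(
    blocks: Sequence[HaplotypeBlock],
    merged: Mapping[str, ChromosomeHaplotype],
    progeny_calls_by_id: Mapping[str, Mapping[tuple[str, int], VcfSiteCall]],
    params: CallerParams = CallerParams(),
) -> list[RecombinationEvent]:
    """Call events for many progeny over one parent's blocks and haplotypes.

    Fragment classes come from the short blocks; crossovers from the
    merged haplotypes plus from short blocks not represented in any
    merged haplotype.
    """
    fragment_classes = ("gene_conversion", "ignored_short", "ambiguous")
    units: list[tuple[HaplotypeBlock, tuple[str, ...]]] = []
    for blk in blocks:
        keep = fragment_classes
        if _co_from_short_block(blk, merged.values()):
            keep = keep + ("crossover",)
        units.append((blk, keep))
    for ch in merged.values():
        units.append((ch.block, ("crossover",)))

    events: list[RecombinationEvent] = []
    for pid in sorted(progeny_calls_by_id):
        calls = progeny_calls_by_id[pid]
        for unit, keep in units:
            unit_events, _ = _call_unit(unit, calls, pid, params, keep)
            events.extend(unit_events)
    return events
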