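"""Parental haplotype-block construction, a/b labelling and map-guided merging.

A haplotype block is an ordered set of phased heterozygous SNPs of one
parent.  Sites are kept only if they are well-supported (depth, per-allele
depth, genotype quality) and pseudo-testcross: heterozygous in the focal
parent, homozygous in the other.  The homozygous parent's allele is
labelled 'a', the focal parent's alternative allele 'b'; downstream event
calling operates purely on these labels.

Blocks on one chromosome are merged into a chromosome-scale haplotype
using per-marker linkage phases: homolog 1 of the merged haplotype is
defined as the homolog carrying allele 'b' at coupling-phase markers and
allele 'a' at repulsion-phase markers.  Blocks containing no mapped SNP
cannot be oriented and are left out of the merged haplotype (they remain
usable as short blocks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from meiorec.formats_io import LinkageMapEntry, VcfSiteCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhasedSite:
    """One phased heterozygous SNP of the focal parent with a/b labels."""

    chrom: str
    pos: int
    hap1_allele: str
    hap2_allele: str
    ab_label_hap1: str = ""  # 'a' or 'b' once assigned
    ab_label_hap2: str = ""
    depth: int = 0
    allele_depths: tuple[int, int] = (0, 0)  # (hap1, hap2) reads
    genotype_quality: float = 0.0
    mapped: bool = False

    def __post_init__(self) -> None:
        if self.hap1_allele == self.hap2_allele:
            raise ValueError("phased site must be heterozygous")
        if self.ab_label_hap1 and {self.ab_label_hap1, self.ab_label_hap2} != {
            "a",
            "b",
        }:
            raise ValueError("ab labels must be one 'a' and one 'b'")

    def swapped(self) -> "PhasedSite":
        """The same site with homologs 1 and 2 exchanged."""
        return replace(
            self,
            hap1_allele=self.hap2_allele,
            hap2_allele=self.hap1_allele,
            ab_label_hap1=self.ab_label_hap2,
            ab_label_hap2=self.ab_label_hap1,
            allele_depths=(self.allele_depths[1], self.allele_depths[0]),
        )

    def label_of_allele(self, allele: str) -> Optional[str]:
        if allele == self.hap1_allele:
            return self.ab_label_hap1
        if allele == self.hap2_allele:
            return self.ab_label_hap2
        return None


@dataclass
class HaplotypeBlock:
    """An ordered run of phased pseudo-testcross SNPs of one parent."""

    parent_id: str
    chrom: str
    block_id: str
    sites: list[PhasedSite]
    source: str = "phased_input"  # or "merged"

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"block {self.block_id}: sites not strictly increasing")

    @property
    def span_start(self) -> int:
        return self.sites[0].pos

    @property
    def span_end(self) -> int:
        return self.sites[-1].pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def hap_labels(self, homolog: int) -> str:
        """Concatenated a/b labels along one homolog (1 or 2)."""
        attr = "ab_label_hap1" if homolog == 1 else "ab_label_hap2"
        return "".join(getattr(s, attr) for s in self.sites)


@dataclass
class ChromosomeHaplotype:
    """A merged, chromosome-scale haplotype for one parent and linkage group."""

    parent_id: str
    linkage_group: str
    block: HaplotypeBlock  # source == "merged"
    member_block_ids: list[str]
    n_mapped_sites: int


def _other_hom_allele(call: VcfSiteCall) -> Optional[str]:
    if call.genotype == "hom_ref":
        return call.ref_allele
    if call.genotype == "hom_alt":
        return call.alt_allele
    return None


def build_parent_blocks(
    phased_groups: Mapping[tuple[str, Optional[str]], list[VcfSiteCall]],
    other_parent_calls: Mapping[tuple[str, int], VcfSiteCall],
    parent_id: str = "P1",
    min_snps: int = 5,
    min_depth: int = 5,
    min_allele_reads: int = 3,
    min_gq: float = 60,
) -> list[HaplotypeBlock]:
    """Filter phase-set groups into pseudo-testcross haplotype blocks.

    A site survives iff its depth is at least ``min_depth``, both alleles
    have at least ``min_allele_reads`` reads, the genotype quality is at
    least ``min_gq``, the focal parent is heterozygous (phased) and the
    other parent is homozygous at that position.  Groups retaining fewer
    than ``min_snps`` sites are discarded.  a/b labels are not assigned
    here; see :func:`assign_ab_labels`.
    """
    blocks: list[HaplotypeBlock] = []
    n_dropped_absent = 0
    for (chrom, phase_set), calls in sorted(
        phased_groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        if phase_set is None:
            continue
        sites = []
        for call in calls:
            if not (call.phased and call.genotype == "het"):
                continue
            if call.depth < min_depth:
                continue
            if min(call.allele_depths) < min_allele_reads:
                continue
            if call.genotype_quality < min_gq:
                continue
            other = other_parent_calls.get((chrom, call.pos))
            if other is None:
                n_dropped_absent += 1
                continue
            if _other_hom_allele(other) is None:
                continue
            h1, h2 = call.hap_alleles
            d1, d2 = call.hap_depths
            sites.append(
                PhasedSite(
                    chrom=chrom,
                    pos=call.pos,
                    hap1_allele=h1,
                    hap2_allele=h2,
                    depth=call.depth,
                    allele_depths=(d1, d2),
                    genotype_quality=call.genotype_quality,
                )
            )
        if len(sites) >= min_snps:
            blocks.append(
                HaplotypeBlock(
                    parent_id=parent_id,
                    chrom=chrom,
                    block_id=str(phase_set),
                    sites=sites,
                )
            )
    if n_dropped_absent:
        logger.info(
            "%s: dropped %d site(s) absent from the other parent's calls",
            parent_id,
            n_dropped_absent,
        )
    return blocks


def assign_ab_labels(
    block: HaplotypeBlock,
    other_parent_calls: Mapping[tuple[str, int], VcfSiteCall],
) -> HaplotypeBlock:
    """Label each site's alleles: the other parent's homozygous allele is 'a'.

    The focal parent's remaining allele is 'b'.  Sites where the other
    parent is homozygous for an allele the focal parent does not carry
    (tri-allelic inconsistency) are dropped with a warning.
    """
    labelled = []
    for site in block.sites:
        other = other_parent_calls.get((site.chrom, site.pos))
        a_allele = _other_hom_allele(other) if other is not None else None
        if a_allele is None:
            logger.warning(
                "%s:%d other parent not homozygous; site dropped",
                site.chrom,
                site.pos,
            )
            continue
        if a_allele == site.hap1_allele:
            labels = ("a", "b")
        elif a_allele == site.hap2_allele:
            labels = ("b", "a")
        else:
            logger.warning(
                "%s:%d other parent homozygous for %s not carried by focal "
                "parent; site dropped",
                site.chrom,
                site.pos,
                a_allele,
            )
            continue
        labelled.append(
            replace(site, ab_label_hap1=labels[0], ab_label_hap2=labels[1])
        )
    return HaplotypeBlock(
        parent_id=block.parent_id,
        chrom=block.chrom,
        block_id=block.block_id,
        sites=labelled,
        source=block.source,
    )


def _orientation_vote(site: PhasedSite, phase: str) -> Optional[bool]:
    """True if the block needs a homolog swap to satisfy the convention.

    Convention: merged homolog 1 carries 'b' at coupling markers and 'a'
    at repulsion markers.
    """
    desired_hap1 = "b" if phase == "coupling" else "a"
    if not site.ab_label_hap1:
        return None
    return site.ab_label_hap1 != desired_hap1


def merge_blocks_with_map(
    blocks: Iterable[HaplotypeBlock],
    linkage_map: Mapping[str, list[LinkageMapEntry]],
) -> dict[str, ChromosomeHaplotype]:
    """Merge labelled blocks into one chromosome-scale haplotype per group.

    Each block containing at least one mapped SNP is oriented so that
    merged homolog 1 carries 'b' at coupling markers and 'a' at repulsion
    markers; conflicting votes within a block are resolved by majority and
    ties exclude the block.  Oriented blocks are concatenated in physical
    order; unmapped blocks are excluded.  The per-block orientation makes
    the merge associative: any grouping of adjacent merges yields the same
    chromosome haplotype.
    """
    site_index: dict[tuple[str, int], HaplotypeBlock] = {}
    for blk in blocks:
        for site in blk.sites:
            site_index[(blk.chrom, site.pos)] = blk

    merged: dict[str, ChromosomeHaplotype] = {}
    for lg, entries in sorted(linkage_map.items()):
        votes: dict[int, list[bool]] = {}
        mapped_positions: dict[int, set[int]] = {}
        block_by_id: dict[int, HaplotypeBlock] = {}
        for entry in entries:
            blk = site_index.get((entry.chrom, entry.pos))
            if blk is None:
                logger.info(
                    "marker %s matches no block; ignored", entry.marker_id
                )
                continue
            site = next(s for s in blk.sites if s.pos == entry.pos)
            vote = _orientation_vote(site, entry.phase)
            if vote is None:
                continue
            key = id(blk)
            block_by_id[key] = blk
            votes.setdefault(key, []).append(vote)
            mapped_positions.setdefault(key, set()).add(entry.pos)

        oriented: list[tuple[HaplotypeBlock, bool]] = []
        for key, blk in block_by_id.items():
            n_swap = sum(votes[key])
            n_keep = len(votes[key]) - n_swap
            if n_swap == n_keep:
                logger.warning(
                    "block %s: tied orientation votes; excluded from merge",
                    blk.block_id,
                )
                continue
            oriented.append((blk, n_swap > n_keep))
        if not oriented:
            continue
        oriented.sort(key=lambda bs: bs[0].span_start)

        chroms = {blk.chrom for blk, _ in oriented}
        if len(chroms) > 1:
            raise ValueError(
                f"linkage group {lg}: member blocks span chromosomes {chroms}"
            )
        parent_ids = {blk.parent_id for blk, _ in oriented}
        if len(parent_ids) > 1:
            raise ValueError(f"linkage group {lg}: blocks from several parents")

        sites: list[PhasedSite] = []
        member_ids: list[str] = []
        prev_end = -1
        n_mapped = 0
        for blk, swap in oriented:
            if blk.span_start <= prev_end:
                logger.warning(
                    "block %s overlaps previous member; excluded", blk.block_id
                )
                continue
            mapped_here = mapped_positions.get(id(blk), set())
            for site in blk.sites:
                out = site.swapped() if swap else site
                if site.pos in mapped_here:
                    out = replace(out, mapped=True)
                    n_mapped += 1
                sites.append(out)
            member_ids.append(blk.block_id)
            prev_end = blk.span_end
        block = HaplotypeBlock(
            parent_id=next(iter(parent_ids)),
            chrom=next(iter(chroms)),
            block_id=f"{lg}_merged",
            sites=sites,
            source="merged",
        )
        merged[lg] = ChromosomeHaplotype(
            parent_id=block.parent_id,
            linkage_group=lg,
            block=block,
            member_block_ids=member_ids,
            n_mapped_sites=n_mapped,
        )
    return merged


def select_pseudo_testcross_sites(
    block: HaplotypeBlock,
    other_parent_calls: Mapping[tuple[str, int], VcfSiteCall],
) -> HaplotypeBlock:
    """Re-verify the pseudo-testcross pattern over a block's sites.

    Construction already enforces heterozygous-focal/homozygous-other, so
    for blocks built here this is the identity; merged haplotypes
    assembled from heterogeneous sources may contain violators, which are
    dropped.
    """
    kept = []
    for site in block.sites:
        other = other_parent_calls.get((site.chrom, site.pos))
        if other is None or _other_hom_allele(other) is None:
            continue
        kept.append(site)
    if len(kept) == len(block.sites):
        return block
    return HaplotypeBlock(
        parent_id=block.parent_id,
        chrom=block.chrom,
        block_id=block.block_id,
        sites=kept,
        source=block.source,
    )


def blocks_from_phased_groups(
    phased_groups: Mapping[tuple[str, Optional[str]], list[VcfSiteCall]],
    parent_id: str,
    source: str = "phased_input",
) -> list[HaplotypeBlock]:
    """Rehydrate already-filtered blocks (e.g. from a block TSV) verbatim.

    No quality filtering is applied; a/b labels are not assigned.
    """
    blocks = []
    for (chrom, block_id), calls in sorted(
        phased_groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        if block_id is None:
            continue
        sites = []
        for call in calls:
            h1, h2 = call.hap_alleles
            d1, d2 = call.hap_depths
            sites.append(
                PhasedSite(
                    chrom=chrom,
                    pos=call.pos,
                    hap1_allele=h1,
                    hap2_allele=h2,
                    depth=call.depth,
                    allele_depths=(d1, d2),
                    genotype_quality=call.genotype_quality,
                )
            )
        blocks.append(
            HaplotypeBlock(
                parent_id=parent_id,
                chrom=chrom,
                block_id=str(block_id),
                sites=sites,
                source=source,
            )
        )
    return blocks
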