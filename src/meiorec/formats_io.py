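"""Readers and writers for the external formats the pipeline touches.

Input side: phase-set-annotated parental VCFs (or an equivalent block TSV
dialect), progeny genotype VCFs, linkage-map TSVs, and SAM/TSV alignment
summaries for the repeat-region read filter.  Output side: the block TSV
dialect and a BED6+ event file.

Internal coordinates are 1-based inclusive (VCF convention); BED output is
converted to 0-based half-open on write and back on read.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import cyvcf2
import numpy as np

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True)
class VcfSiteCall:
    """A single-sample genotype call at one biallelic SNP site."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype: str  # one of GENOTYPES
    phased: bool = False
    phase_set: Optional[str] = None
    depth: int = 0
    allele_depths: tuple[int, int] = (0, 0)  # (ref, alt) reads
    genotype_quality: float = 0.0
    hap_order: tuple[int, int] = (0, 1)  # allele index (0=ref,1=alt) on hap1, hap2

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if any(d < 0 for d in self.allele_depths):
            raise ValueError("allele depths must be >= 0")
        if self.phased and self.phase_set is None:
            raise ValueError("phased call requires a phase_set")

    @property
    def hap_alleles(self) -> tuple[str, str]:
        """Alleles on (haplotype 1, haplotype 2); meaningful when phased."""
        alleles = (self.ref_allele, self.alt_allele)
        return alleles[self.hap_order[0]], alleles[self.hap_order[1]]

    @property
    def hap_depths(self) -> tuple[int, int]:
        """Read depths of the (haplotype 1, haplotype 2) alleles."""
        return (
            self.allele_depths[self.hap_order[0]],
            self.allele_depths[self.hap_order[1]],
        )

    def phased_key(self) -> tuple:
        """Dialect-independent identity of a phased heterozygous call."""
        return (
            self.chrom,
            self.pos,
            self.hap_alleles,
            self.hap_depths,
            self.depth,
            self.genotype_quality,
        )


@dataclass(frozen=True)
class LinkageMapEntry:
    """One mapped SNP marker: physical location, genetic position and phase.

    ``phase`` is per-marker relative to the linkage group's reference
    homolog: ``coupling`` markers have their 'b' allele on the reference
    homolog, ``repulsion`` markers their 'a' allele.
    """

    marker_id: str
    linkage_group: str
    genetic_pos: float  # centimorgans
    phase: str  # {"coupling", "repulsion"}
    chrom: str = field(default="", compare=False)
    pos: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.phase not in ("coupling", "repulsion"):
            raise ValueError(f"unknown linkage phase {self.phase!r}")
        if self.genetic_pos < 0:
            raise ValueError("genetic_pos must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    """Alignment summary of one read: length, NM, AS and optional XS."""

    read_length: int
    edit_distance: int
    best_score: float
    second_best_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.edit_distance < 0:
            raise ValueError("edit_distance must be >= 0")


_MARKER_RE = re.compile(r"^C(\d+)_(\d+)$")


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Decode a ``C<cc>_<pos>`` marker name into (chromosome, 1-based bp).

    >>> parse_marker_id("C01_400706")
    ('Chr01', 400706)
    """
    m = _MARKER_RE.match(marker_id)
    if not m:
        raise ValueError(f"marker id {marker_id!r} does not match C<cc>_<pos>")
    cc, pos = m.groups()
    return f"Chr{int(cc):02d}", int(pos)


def _classify_gt(alleles: Sequence[int]) -> str:
    if any(a < 0 for a in alleles):
        return "missing"
    if alleles[0] == alleles[1] == 0:
        return "hom_ref"
    if alleles[0] == alleles[1]:
        return "hom_alt"
    return "het"


def read_phased_parent_vcf(
    path: str | Path, parent_id: Optional[str] = None
) -> dict[tuple[str, str], list[VcfSiteCall]]:
    """Read a phased single-parent VCF into phase-set groups.

    Returns ``{(chrom, phase_set): [VcfSiteCall, ...]}`` with records sorted
    by position within each group.  Only biallelic SNPs are used: indels are
    skipped silently (the upstream caller's convention), multi-allelic
    records are dropped with a warning, and unphased or phase-set-less
    records are returned under phase_set ``None`` so they remain available
    as plain genotype lookups.
    """
    path = str(path)
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    sample_idx = 0
    if parent_id is not None and parent_id in vcf.samples:
        sample_idx = vcf.samples.index(parent_id)

    groups: dict[tuple[str, Optional[str]], list[VcfSiteCall]] = {}
    for var in vcf:
        if not var.is_snp:
            continue  # indels and other non-SNP records
        if len(var.ALT) != 1:
            logger.warning(
                "dropping multi-allelic record %s:%d", var.CHROM, var.POS
            )
            continue
        gt = var.genotypes[sample_idx]
        alleles, phased = gt[:-1], bool(gt[-1])
        if len(alleles) != 2:
            logger.warning(
                "dropping non-diploid genotype at %s:%d", var.CHROM, var.POS
            )
            continue
        genotype = _classify_gt(alleles)

        ps = None
        ps_arr = var.format("PS")
        if ps_arr is not None:
            val = np.asarray(ps_arr[sample_idx]).ravel()[0]
            try:
                val = val.item()
            except AttributeError:
                pass
            if val not in (None, ".", -2147483648):
                ps = str(val)
        phased = phased and genotype == "het" and ps is not None

        ad = var.format("AD")
        if ad is not None:
            ad_pair = (max(int(ad[sample_idx][0]), 0), max(int(ad[sample_idx][1]), 0))
        else:
            ad_pair = (0, 0)
        dp = var.format("DP")
        depth = (
            int(np.asarray(dp[sample_idx]).ravel()[0])
            if dp is not None
            else sum(ad_pair)
        )
        gq = float(var.gt_quals[sample_idx]) if var.gt_quals is not None else 0.0

        hap_order = (0, 1)
        if phased:
            hap_order = (alleles[0], alleles[1])

        call = VcfSiteCall(
            chrom=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_allele=var.ALT[0],
            genotype=genotype,
            phased=phased,
            phase_set=ps if phased else None,
            depth=max(depth, 0),
            allele_depths=ad_pair,
            genotype_quality=max(gq, 0.0),
            hap_order=hap_order,
        )
        key = (var.CHROM, call.phase_set)
        groups.setdefault(key, []).append(call)

    for key in groups:
        groups[key].sort(key=lambda c: c.pos)
    return groups


BLOCK_TSV_COLUMNS = [
    "chrom",
    "block_id",
    "pos",
    "hap1_allele",
    "hap2_allele",
    "depth",
    "depth_allele1",
    "depth_allele2",
    "genotype_quality",
]


def read_block_tsv(path: str | Path) -> dict[tuple[str, str], list[VcfSiteCall]]:
    """Read the phased-block TSV dialect.

    Equivalent in structure to :func:`read_phased_parent_vcf`: a dict keyed
    by ``(chrom, block_id)`` of position-sorted phased heterozygous calls.
    hap1/hap2 alleles define the phasing directly (hap1 is stored as the
    REF-slot allele).
    """
    groups: dict[tuple[str, str], list[VcfSiteCall]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in BLOCK_TSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"block TSV missing column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):
            h1, h2 = row["hap1_allele"], row["hap2_allele"]
            if h1 == h2:
                raise ValueError(
                    f"line {i}: hap1_allele == hap2_allele ({h1}); "
                    "phased sites must be heterozygous"
                )
            call = VcfSiteCall(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=h1,
                alt_allele=h2,
                genotype="het",
                phased=True,
                phase_set=row["block_id"],
                depth=int(row["depth"]),
                allele_depths=(int(row["depth_allele1"]), int(row["depth_allele2"])),
                genotype_quality=float(row["genotype_quality"]),
                hap_order=(0, 1),
            )
            key = (call.chrom, call.phase_set)
            group = groups.setdefault(key, [])
            if group and call.pos <= group[-1].pos:
                raise ValueError(
                    f"line {i}: positions not strictly increasing within block "
                    f"{call.phase_set} ({call.pos} after {group[-1].pos})"
                )
            group.append(call)
    return groups


def write_block_tsv(
    groups: dict[tuple[str, str], list[VcfSiteCall]], path: str | Path
) -> None:
    """Write phase-set groups in the block TSV dialect (deterministic order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(BLOCK_TSV_COLUMNS)
        for (chrom, block_id) in sorted(groups, key=lambda k: (k[0], str(k[1]))):
            for call in groups[(chrom, block_id)]:
                h1, h2 = call.hap_alleles
                d1, d2 = call.hap_depths
                writer.writerow(
                    [
                        chrom,
                        block_id,
                        call.pos,
                        h1,
                        h2,
                        call.depth,
                        d1,
                        d2,
                        _fmt_float(call.genotype_quality),
                    ]
                )


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def read_linkage_map(path: str | Path) -> dict[str, list[LinkageMapEntry]]:
    """Read a linkage-map TSV (marker_id, linkage_group, genetic_pos, phase).

    Entries are sorted by genetic position within each linkage group; ties
    are broken by physical position ascending.
    """
    entries: dict[str, list[LinkageMapEntry]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        required = ["marker_id", "linkage_group", "genetic_pos", "phase"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"linkage map missing column(s): {', '.join(missing)}")
        n = 0
        for row in reader:
            chrom, pos = parse_marker_id(row["marker_id"])
            entry = LinkageMapEntry(
                marker_id=row["marker_id"],
                linkage_group=row["linkage_group"],
                genetic_pos=float(row["genetic_pos"]),
                phase=row["phase"],
                chrom=chrom,
                pos=pos,
            )
            entries.setdefault(entry.linkage_group, []).append(entry)
            n += 1
    if n == 0:
        logger.warning("linkage map %s contains no markers", path)
    for lg in entries:
        entries[lg].sort(key=lambda e: (e.genetic_pos, e.pos))
    return entries


def write_linkage_map(
    entries: dict[str, list[LinkageMapEntry]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker_id", "linkage_group", "genetic_pos", "phase"])
        for lg in sorted(entries):
            for e in entries[lg]:
                writer.writerow([e.marker_id, lg, _fmt_float(e.genetic_pos), e.phase])


def filter_alignment_records(
    records: Iterable[AlignmentRecord],
    max_edit_fraction: float = 0.08,
    min_best_score: float = 60,
    rule: str = "methods",
) -> list[AlignmentRecord]:
    """Keep reads uniquely mapped outside repeat regions.

    Both rules require an edit distance of at most ``max_edit_fraction`` of
    the read length.  The score condition differs:

    - ``rule="methods"``: best score >= ``min_best_score`` and the second
      best strictly below the best;
    - ``rule="results"``: best score at least ``min_best_score`` higher than
      the second best.

    An absent second-best score is treated as -inf (the read has no
    competing placement), so it passes either score margin.  The filter is
    pure, order-preserving and idempotent.
    """
    if rule not in ("methods", "results"):
        raise ValueError(f"unknown rule {rule!r}")
    kept = []
    for rec in records:
        if rec.edit_distance > max_edit_fraction * rec.read_length:
            continue
        xs = rec.second_best_score
        if rule == "methods":
            ok = rec.best_score >= min_best_score and (
                xs is None or xs < rec.best_score
            )
        else:
            ok = xs is None or (rec.best_score - xs) >= min_best_score
        if ok:
            kept.append(rec)
    return kept


def read_alignment_records(path: str | Path) -> list[AlignmentRecord]:
    """Load alignment summaries from a SAM file or a 4-column TSV.

    SAM input uses query length plus the NM/AS/XS tags (records missing NM
    or AS, or unmapped, are skipped).  TSV input needs columns
    read_length, edit_distance, best_score, second_best_score (empty/NA for
    absent).
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        import pysam

        records = []
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for aln in af:
                if aln.is_unmapped or not aln.query_length:
                    continue
                if not (aln.has_tag("NM") and aln.has_tag("AS")):
                    continue
                xs = aln.get_tag("XS") if aln.has_tag("XS") else None
                records.append(
                    AlignmentRecord(
                        read_length=aln.query_length,
                        edit_distance=int(aln.get_tag("NM")),
                        best_score=float(aln.get_tag("AS")),
                        second_best_score=None if xs is None else float(xs),
                    )
                )
        return records

    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = ["read_length", "edit_distance", "best_score", "second_best_score"]
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(
                f"alignment TSV missing column(s): {', '.join(missing)}"
            )
        for row in reader:
            raw_xs = (row["second_best_score"] or "").strip()
            xs = None if raw_xs in ("", "NA", ".") else float(raw_xs)
            records.append(
                AlignmentRecord(
                    read_length=int(row["read_length"]),
                    edit_distance=int(row["edit_distance"]),
                    best_score=float(row["best_score"]),
                    second_best_score=xs,
                )
            )
    return records


BED_TRACK_HEADER = 'track name=meiorec_events description="recombination events"'


@dataclass(frozen=True)
class BedEvent:
    """An event record as serialized to/from the BED6+ file."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    event_class: str
    parent_of_origin: str
    progeny_id: str
    n_snps: int


def write_events_bed(events: Iterable, path: str | Path) -> None:
    """Write events as BED6+ (0-based half-open), name ``class:parent:progeny``.

    Events must carry chrom, start, end (1-based inclusive), event_class,
    progeny_id, parent_of_origin and n_snps.  Output is sorted by
    (chrom, start) and byte-deterministic.
    """
    rows = []
    for ev in events:
        rows.append(
            (
                ev.chrom,
                ev.start - 1,
                ev.end,
                f"{ev.event_class}:{ev.parent_of_origin}:{ev.progeny_id}",
                ev.n_snps,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w", newline="") as fh:
        fh.write(BED_TRACK_HEADER + "\n")
        for chrom, start, end, name, n_snps in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{n_snps}\t.\n")


def read_events_bed(path: str | Path) -> list[BedEvent]:
    """Read back a BED6+ event file written by :func:`write_events_bed`."""
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed BED line: {line!r}")
            cls, parent, progeny = fields[3].split(":", 2)
            events.append(
                BedEvent(
                    chrom=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    event_class=cls,
                    parent_of_origin=parent,
                    progeny_id=progeny,
                    n_snps=int(fields[4]),
                )
            )
    return events


def write_calls_vcf(
    calls: Iterable[VcfSiteCall],
    path: str | Path,
    sample: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write single-sample calls as an uncompressed VCF 4.2 text file.

    Emits GT (phased with a PS tag where applicable), DP, AD and GQ.
    Records are sorted by (chrom, pos); output is byte-deterministic.
    """
    import pysam

    calls = sorted(calls, key=lambda c: (c.chrom, c.pos))
    header = pysam.VariantHeader()
    header.add_meta("source", "meiorec")
    contigs: dict[str, int] = dict(contig_lengths or {})
    for call in calls:
        contigs.setdefault(call.chrom, 0)
        contigs[call.chrom] = max(contigs[call.chrom], call.pos)
    for chrom in sorted(contigs):
        header.contigs.add(chrom, length=contigs[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("PS", 1, "Integer", "Phase set")
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos,
                alleles=(call.ref_allele, call.alt_allele),
            )
            fmt = rec.samples[sample]
            if call.genotype == "missing":
                fmt["GT"] = (None, None)
            elif call.phased:
                fmt["GT"] = call.hap_order
                fmt.phased = True
                fmt["PS"] = int(call.phase_set)
            else:
                gt = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
                fmt["GT"] = gt[call.genotype]
            fmt["DP"] = call.depth
            fmt["AD"] = list(call.allele_depths)
            fmt["GQ"] = int(round(call.genotype_quality))
            out.write(rec)


def read_vcf_calls(
    path: str | Path, sample: Optional[str] = None
) -> dict[tuple[str, int], VcfSiteCall]:
    """Read a single-sample VCF into a (chrom, pos) -> call lookup."""
    groups = read_phased_parent_vcf(path, parent_id=sample)
    lookup: dict[tuple[str, int], VcfSiteCall] = {}
    for calls in groups.values():
        for call in calls:
            lookup[(call.chrom, call.pos)] = call
    return lookup
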