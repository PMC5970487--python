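"""Forward simulator of outbred F1 meiosis for desk-scale pipeline testing.

Two heterozygous outbred parents are drawn with a configurable mix of
pseudo-testcross (ab×aa, aa×ab) and doubly heterozygous (ab×ab) SNPs.
Each progeny receives one recombinant gamete per parent: crossover counts
are Poisson per chromosome with uniform breakpoints, and gene-conversion
tracts (Poisson counts, configurable length distribution) copy the
opposite homolog onto the gamete.  Sequencing is emulated per site with
Poisson depth, binomial allele sampling, per-read miscalls, and a
likelihood-based diploid genotype caller that emits GT/DP/AD/GQ, so the
pipeline's depth and quality filters are exercisable.  Ground-truth event
tables allow sensitivity/precision scoring of the caller.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from meiorec.formats_io import LinkageMapEntry, VcfSiteCall

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

SEG_ABXAA, SEG_AAXAB, SEG_ABXAB = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the simulated F1 design.

    Defaults describe the reference desk-scale scenario: two 1-Mb
    chromosomes at one SNP per kb, ten progeny sequenced to 30x with
    error-free reads, one crossover and twenty gene-conversion tracts
    (uniform 50-1500 bp) per chromosome per meiosis.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    snp_density: float = 1e-3
    fraction_abxaa: float = 0.4
    fraction_aaxab: float = 0.4
    fraction_abxab: float = 0.2
    co_rate_per_chrom: float = 1.0
    gc_rate_per_chrom: float = 20.0
    gc_length_dist: tuple = ("uniform", 50, 1500)  # or ("geometric", mean_bp)
    mean_depth: float = 30.0
    error_rate: float = 0.0
    n_progeny: int = 10
    mapped_marker_fraction: float = 0.05
    phase_break_prob: float = 0.08
    min_event_separation_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fraction_abxaa + self.fraction_aaxab + self.fraction_abxab
        if not math.isclose(fr, 1.0, abs_tol=1e-9):
            raise ValueError("segregation-type fractions must sum to 1")
        for name in ("co_rate_per_chrom", "gc_rate_per_chrom", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth record of one simulated meiotic event."""

    progeny_id: str
    parent_of_origin: str
    chrom: str
    event_class: str  # "CO" or "GC"
    start: int  # CO: start == end == breakpoint bp
    end: int
    n_snps_covered: int = 0  # focal-parent het sites inside a GC tract


@dataclass
class ChromData:
    """Simulated truth for one chromosome: sites, alleles, parent phases."""

    name: str
    length: int
    positions: np.ndarray  # sorted 1-based, no duplicates
    ref: np.ndarray  # base per site
    alt: np.ndarray
    seg_type: np.ndarray  # SEG_* per site
    haps: dict[str, np.ndarray]  # parent -> (2, n) allele index array

    def het_mask(self, parent: str) -> np.ndarray:
        h = self.haps[parent]
        return h[0] != h[1]

    def pt_mask(self, parent: str) -> np.ndarray:
        """Pseudo-testcross sites of ``parent`` (het here, hom in the other)."""
        want = SEG_ABXAA if parent == "P1" else SEG_AAXAB
        return self.seg_type == want


@dataclass
class SimulatedParents:
    """Parental truth plus observed (noisy) parental data products."""

    config: SimulationConfig
    chroms: list[ChromData]
    phased_groups: dict[str, dict[tuple[str, str], list[VcfSiteCall]]]
    calls: dict[str, dict[tuple[str, int], VcfSiteCall]]
    linkage_maps: dict[str, dict[str, list[LinkageMapEntry]]]


@dataclass
class SimulatedDataset:
    """A full simulate run: parents, progeny genotypes and truth events."""

    config: SimulationConfig
    parents: SimulatedParents
    progeny_ids: list[str]
    progeny_calls: dict[str, dict[tuple[str, int], VcfSiteCall]]
    truth: list[TruthEvent]
    gamete_homologs: dict[tuple[str, str, str], np.ndarray]
    # (progeny, parent, chrom) -> per-site parental homolog of origin (0/1)


def call_genotype(
    n_ref: int, n_alt: int, call_error: float = 0.01
) -> tuple[str, float]:
    """Likelihood-based diploid genotype call from allele read counts.

    Compares hom_ref / het / hom_alt binomial likelihoods with a fixed
    per-read miscall probability; GQ is the Phred-scaled likelihood ratio
    of the best to the second-best genotype, capped at 99.  Monotone in
    the strength of evidence, so depth and quality thresholds bite.
    """
    depth = n_ref + n_alt
    if depth == 0:
        return "missing", 0.0
    le, l1e = math.log(call_error), math.log1p(-call_error)
    ll = {
        "hom_ref": n_ref * l1e + n_alt * le,
        "het": depth * math.log(0.5),
        "hom_alt": n_alt * l1e + n_ref * le,
    }
    ranked = sorted(ll, key=ll.get, reverse=True)
    gq = min(99.0, (ll[ranked[0]] - ll[ranked[1]]) * 10.0 / math.log(10.0))
    return ranked[0], round(gq, 2)


def _sample_reads(
    allele_pair: tuple[int, int],
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Read counts (ref, alt) for a true genotype under the noise model."""
    x, y = allele_pair
    if x == y:
        n_from = [depth, 0] if x == 0 else [0, depth]
    else:
        n0 = int(rng.binomial(depth, 0.5))
        n_from = [n0, depth - n0]
        if x == 1:
            n_from.reverse()
    if error_rate > 0:
        flips0 = int(rng.binomial(n_from[0], error_rate))
        flips1 = int(rng.binomial(n_from[1], error_rate))
        n_from = [n_from[0] - flips0 + flips1, n_from[1] - flips1 + flips0]
    return n_from[0], n_from[1]


def _observe_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    true_pair: tuple[int, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    phase_set: Optional[str] = None,
    hap_order: Optional[tuple[int, int]] = None,
) -> VcfSiteCall:
    depth = int(rng.poisson(config.mean_depth))
    n_ref, n_alt = _sample_reads(true_pair, depth, config.error_rate, rng)
    genotype, gq = call_genotype(n_ref, n_alt)
    phased = (
        genotype == "het"
        and phase_set is not None
        and hap_order is not None
        and true_pair[0] != true_pair[1]
    )
    return VcfSiteCall(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        genotype=genotype,
        phased=phased,
        phase_set=phase_set if phased else None,
        depth=depth,
        allele_depths=(n_ref, n_alt),
        genotype_quality=gq,
        hap_order=hap_order if phased else (0, 1),
    )


def simulate_parents(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedParents:
    """Draw two phased outbred parents, their noisy observations and maps.

    SNP positions are sampled without replacement at ``snp_density``; each
    site gets a segregation type from the configured mix and random phase
    per heterozygous parent.  A ``mapped_marker_fraction`` subset of each
    parent's pseudo-testcross sites is emitted as linkage-map rows whose
    per-marker phase is true (relative to the parent's homolog 1).
    Observed parental calls carry simulated depth/AD/GQ so the block
    filters are exercised.  Deterministic given ``config.seed``.
    """
    if config.snp_density * config.chrom_length_bp < 10:
        raise ValueError("degenerate configuration: fewer than ~10 SNPs expected")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chroms: list[ChromData] = []
    for c in range(config.n_chromosomes):
        name = f"Chr{c + 1:02d}"
        L = config.chrom_length_bp
        n = int(rng.binomial(L, config.snp_density))
        positions = np.sort(rng.choice(L, size=n, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        seg = rng.choice(
            [SEG_ABXAA, SEG_AAXAB, SEG_ABXAB],
            size=n,
            p=[config.fraction_abxaa, config.fraction_aaxab, config.fraction_abxab],
        )
        haps: dict[str, np.ndarray] = {}
        for parent, het_types in (("P1", (SEG_ABXAA, SEG_ABXAB)), ("P2", (SEG_AAXAB, SEG_ABXAB))):
            hap = np.zeros((2, n), dtype=np.int8)
            het = np.isin(seg, het_types)
            flip = rng.integers(0, 2, size=n).astype(bool)
            hap[0, het] = np.where(flip[het], 1, 0)
            hap[1, het] = 1 - hap[0, het]
            hom_allele = rng.integers(0, 2, size=n).astype(np.int8)
            hap[0, ~het] = hom_allele[~het]
            hap[1, ~het] = hom_allele[~het]
            haps[parent] = hap
        chroms.append(
            ChromData(
                name=name,
                length=L,
                positions=positions,
                ref=_BASES[ref_idx],
                alt=_BASES[alt_idx],
                seg_type=seg,
                haps=haps,
            )
        )

    phased_groups: dict[str, dict[tuple[str, str], list[VcfSiteCall]]] = {}
    calls: dict[str, dict[tuple[str, int], VcfSiteCall]] = {}
    linkage_maps: dict[str, dict[str, list[LinkageMapEntry]]] = {}
    for parent in ("P1", "P2"):
        other = "P2" if parent == "P1" else "P1"
        groups: dict[tuple[str, str], list[VcfSiteCall]] = {}
        lookup: dict[tuple[str, int], VcfSiteCall] = {}
        lmap: dict[str, list[LinkageMapEntry]] = {}
        for ci, chrom in enumerate(chroms):
            het = chrom.het_mask(parent)
            het_idx = np.flatnonzero(het)
            # phase-set segmentation of the parent's het sites
            ps_of: dict[int, str] = {}
            current: Optional[str] = None
            breaks = rng.random(size=len(het_idx)) < config.phase_break_prob
            for j, i in enumerate(het_idx):
                if current is None or (j > 0 and breaks[j]):
                    current = str(int(chrom.positions[i]))
                ps_of[int(i)] = current
            # mapped-marker subset among this parent's pseudo-testcross sites
            pt_idx = np.flatnonzero(chrom.pt_mask(parent))
            mapped = pt_idx[
                rng.random(size=len(pt_idx)) < config.mapped_marker_fraction
            ]
            mapped_set = set(int(i) for i in mapped)

            hap = chrom.haps[parent]
            other_hap = chrom.haps[other]
            entries: list[LinkageMapEntry] = []
            for i in range(len(chrom.positions)):
                pos = int(chrom.positions[i])
                true_pair = (int(hap[0, i]), int(hap[1, i]))
                call = _observe_site(
                    chrom.name,
                    pos,
                    str(chrom.ref[i]),
                    str(chrom.alt[i]),
                    true_pair,
                    config,
                    rng,
                    phase_set=ps_of.get(i),
                    hap_order=true_pair if true_pair[0] != true_pair[1] else None,
                )
                lookup[(chrom.name, pos)] = call
                if call.phased:
                    groups.setdefault((chrom.name, call.phase_set), []).append(call)
                if i in mapped_set:
                    # 'b' is the allele the other parent lacks; phase is
                    # coupling when the parent's homolog 1 carries it
                    b_idx = 1 - int(other_hap[0, i])
                    phase = "coupling" if int(hap[0, i]) == b_idx else "repulsion"
                    entries.append(
                        LinkageMapEntry(
                            marker_id=f"C{ci + 1:02d}_{pos}",
                            linkage_group=chrom.name,
                            genetic_pos=round(pos / chrom.length * 100.0, 6),
                            phase=phase,
                            chrom=chrom.name,
                            pos=pos,
                        )
                    )
            if entries:
                entries.sort(key=lambda e: (e.genetic_pos, e.pos))
                lmap[chrom.name] = entries
        for key in groups:
            groups[key].sort(key=lambda cl: cl.pos)
        phased_groups[parent] = groups
        calls[parent] = lookup
        linkage_maps[parent] = lmap
    return SimulatedParents(
        config=config,
        chroms=chroms,
        phased_groups=phased_groups,
        calls=calls,
        linkage_maps=linkage_maps,
    )


def _draw_gc_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    dist = config.gc_length_dist
    if dist[0] == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    if dist[0] == "geometric":
        return int(rng.geometric(1.0 / dist[1]))
    raise ValueError(f"unknown gc_length_dist {dist!r}")


def simulate_meiosis(
    chrom: ChromData,
    parent: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[TruthEvent]]:
    """One meiosis of ``parent`` on ``chrom``.

    Returns (gamete allele indices per site, homolog of origin per site,
    truth events).  Crossover counts are Poisson with uniform breakpoints;
    the gamete alternates homologs across breakpoints.  Gene-conversion
    tracts (Poisson counts, lengths from the configured distribution) copy
    the opposite homolog.  Events are re-drawn until they keep
    ``min_event_separation_bp`` of clearance from each other: without this
    the base-haplotype segment between two nearby events is itself a short
    opposite-flanked fragment, making the truth class of the region
    ambiguous by construction.  Truth records are emitted for every event
    regardless of SNP coverage.
    """
    L = chrom.length
    sep = config.min_event_separation_bp
    n_co = int(rng.poisson(config.co_rate_per_chrom))
    breakpoints: list[int] = []
    for _ in range(n_co):
        for _attempt in range(1000):
            b = int(rng.integers(1, L))
            if all(abs(b - other) > sep for other in breakpoints):
                breakpoints.append(b)
                break
        else:  # pragma: no cover
            logger.warning("could not place breakpoint with separation; skipped")
    breakpoints.sort()
    start_hom = int(rng.integers(0, 2))

    # homolog of origin at a site = starting homolog flipped once per
    # breakpoint strictly left of the site
    crossings = np.searchsorted(breakpoints, chrom.positions - 1, side="right")
    hom = ((start_hom + crossings) % 2).astype(np.int8)

    n_gc = int(rng.poisson(config.gc_rate_per_chrom))
    tracts: list[tuple[int, int]] = []
    for _ in range(n_gc):
        for _attempt in range(1000):
            length = min(_draw_gc_length(config, rng), L)
            start = int(rng.integers(1, L - length + 2))
            end = start + length - 1
            if any(start - sep <= b <= end + sep for b in breakpoints):
                continue
            if any(not (end + sep < s or start - sep > e) for s, e in tracts):
                continue
            tracts.append((start, end))
            break
        else:  # pragma: no cover - only under absurdly dense configs
            logger.warning("could not place GC tract without overlap; skipped")
    tracts.sort()

    het = chrom.het_mask(parent)
    truth: list[TruthEvent] = []
    for b in breakpoints:
        truth.append(
            TruthEvent(
                progeny_id="",
                parent_of_origin=parent,
                chrom=chrom.name,
                event_class="CO",
                start=b,
                end=b,
            )
        )
    for start, end in tracts:
        inside = (chrom.positions >= start) & (chrom.positions <= end)
        hom[inside] = 1 - hom[inside]
        truth.append(
            TruthEvent(
                progeny_id="",
                parent_of_origin=parent,
                chrom=chrom.name,
                event_class="GC",
                start=start,
                end=end,
                n_snps_covered=int(np.sum(inside & het)),
            )
        )

    hap = chrom.haps[parent]
    gamete = hap[hom, np.arange(len(chrom.positions))]
    return gamete, hom, truth


def emit_genotypes(
    gametes: Mapping[str, np.ndarray],
    chrom: ChromData,
    config: SimulationConfig,
    rng: np.random.Generator,
    out: dict[tuple[str, int], VcfSiteCall],
) -> None:
    """Observe one progeny's genotypes on one chromosome.

    ``gametes`` maps parent id to the gamete allele-index array.  Depth is
    Poisson(``mean_depth``); reads split binomially between the two true
    alleles and miscall with ``error_rate``; GT/DP/AD/GQ come from
    :func:`call_genotype`.  Results are added to ``out`` keyed by
    (chrom, pos).
    """
    g1, g2 = gametes["P1"], gametes["P2"]
    for i in range(len(chrom.positions)):
        pos = int(chrom.positions[i])
        call = _observe_site(
            chrom.name,
            pos,
            str(chrom.ref[i]),
            str(chrom.alt[i]),
            (int(g1[i]), int(g2[i])),
            config,
            rng,
        )
        out[(chrom.name, pos)] = call


def simulate_dataset(
    config: SimulationConfig, parents: Optional[SimulatedParents] = None
) -> SimulatedDataset:
    """Run the full simulation: parents, meioses, progeny observations.

    Uses a single seeded random stream, so the whole dataset is
    reproducible from ``config.seed`` alone.
    """
    rng = np.random.default_rng(config.seed)
    if parents is None:
        parents = simulate_parents(config, rng)

    progeny_ids = [f"progeny{k + 1:02d}" for k in range(config.n_progeny)]
    truth: list[TruthEvent] = []
    gamete_homologs: dict[tuple[str, str, str], np.ndarray] = {}
    progeny_calls: dict[str, dict[tuple[str, int], VcfSiteCall]] = {}
    for pid in progeny_ids:
        calls: dict[tuple[str, int], VcfSiteCall] = {}
        for chrom in parents.chroms:
            gametes = {}
            for parent in ("P1", "P2"):
                gamete, hom, events = simulate_meiosis(chrom, parent, config, rng)
                gametes[parent] = gamete
                gamete_homologs[(pid, parent, chrom.name)] = hom
                truth.extend(replace(ev, progeny_id=pid) for ev in events)
            emit_genotypes(gametes, chrom, config, rng, calls)
        progeny_calls[pid] = calls
    return SimulatedDataset(
        config=config,
        parents=parents,
        progeny_ids=progeny_ids,
        progeny_calls=progeny_calls,
        truth=truth,
        gamete_homologs=gamete_homologs,
    )


def recovery_compare(
    called_events: Sequence,
    truth: Sequence[TruthEvent],
    expected_events: Sequence,
    informative_sites: Mapping[tuple[str, str, str], Sequence[int]],
    pt_site_positions: Optional[Mapping[tuple[str, str], Sequence[int]]] = None,
    tolerance_bp: int = 0,
) -> dict:
    """Score called events against simulator ground truth.

    A truth GC counts as *eligible* when the pipeline could in principle
    call it: ``expected_events`` — the classification of the true
    inherited homolog labels at the pipeline's informative sites — must
    contain a gene conversion overlapping the tract (and analogously a
    crossover interval containing the breakpoint).  Sensitivity is
    computed over eligible truth events; precision over all called
    events.  Ineligible truth events are assigned a diagnostic reason:
    too few SNPs in the tract, a sub-threshold SNP span, genotype-filter
    losses, or missing flanks.
    """
    exp_gc: dict[tuple[str, str, str], list] = {}
    exp_co: dict[tuple[str, str, str], list] = {}
    for ev in expected_events:
        key = (ev.progeny_id, ev.parent_of_origin, ev.chrom)
        if ev.event_class == "gene_conversion":
            exp_gc.setdefault(key, []).append(ev)
        elif ev.event_class == "crossover":
            exp_co.setdefault(key, []).append(ev)
    called_gc: dict[tuple[str, str, str], list] = {}
    called_co: dict[tuple[str, str, str], list] = {}
    for ev in called_events:
        key = (ev.progeny_id, ev.parent_of_origin, ev.chrom)
        if ev.event_class == "gene_conversion":
            called_gc.setdefault(key, []).append(ev)
        elif ev.event_class == "crossover":
            called_co.setdefault(key, []).append(ev)

    miss_reasons: dict[str, int] = {}
    n_eligible_gc = n_recovered_gc = 0
    n_eligible_co = n_recovered_co = 0
    for tr in truth:
        key = (tr.progeny_id, tr.parent_of_origin, tr.chrom)
        if tr.event_class == "GC":
            eligible = any(
                ev.start <= tr.end and ev.end >= tr.start
                for ev in exp_gc.get(key, [])
            )
            if eligible:
                n_eligible_gc += 1
                if any(
                    ev.start <= tr.end and ev.end >= tr.start
                    for ev in called_gc.get(key, [])
                ):
                    n_recovered_gc += 1
                else:
                    miss_reasons["gc_called_elsewhere"] = (
                        miss_reasons.get("gc_called_elsewhere", 0) + 1
                    )
            else:
                reason = _gc_ineligibility_reason(
                    tr, informative_sites.get(key, ()), pt_site_positions
                )
                miss_reasons[reason] = miss_reasons.get(reason, 0) + 1
        else:
            lo, hi = tr.start - tolerance_bp, tr.start + tolerance_bp
            eligible = any(
                ev.start <= hi and ev.end >= lo for ev in exp_co.get(key, [])
            )
            if eligible:
                n_eligible_co += 1
                if any(
                    ev.start <= hi and ev.end >= lo for ev in called_co.get(key, [])
                ):
                    n_recovered_co += 1
            else:
                miss_reasons["co_short_flank"] = (
                    miss_reasons.get("co_short_flank", 0) + 1
                )

    truth_gc = [tr for tr in truth if tr.event_class == "GC"]
    truth_co = [tr for tr in truth if tr.event_class == "CO"]
    n_called_gc = sum(len(v) for v in called_gc.values())
    n_called_co = sum(len(v) for v in called_co.values())
    n_precise_gc = 0
    for key, evs in called_gc.items():
        for ev in evs:
            if any(
                tr.start <= ev.end and tr.end >= ev.start
                for tr in truth_gc
                if (tr.progeny_id, tr.parent_of_origin, tr.chrom) == key
            ):
                n_precise_gc += 1
    n_precise_co = 0
    for key, evs in called_co.items():
        for ev in evs:
            if any(
                ev.start - tolerance_bp <= tr.start <= ev.end + tolerance_bp
                for tr in truth_co
                if (tr.progeny_id, tr.parent_of_origin, tr.chrom) == key
            ):
                n_precise_co += 1

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    def _consistency(called: dict, expected: dict, n_called: int) -> float:
        # fraction of called events identical to an information-optimal
        # expected event; separates caller defects from SNP-coverage limits
        exp_keys = {
            (k, ev.start, ev.end) for k, evs in expected.items() for ev in evs
        }
        n = sum(
            1
            for k, evs in called.items()
            for ev in evs
            if (k, ev.start, ev.end) in exp_keys
        )
        return _ratio(n, n_called)

    return {
        "gc": {
            "n_truth": len(truth_gc),
            "n_eligible": n_eligible_gc,
            "n_recovered": n_recovered_gc,
            "n_called": n_called_gc,
            "sensitivity": _ratio(n_recovered_gc, n_eligible_gc),
            "precision": _ratio(n_precise_gc, n_called_gc),
            "consistency": _consistency(called_gc, exp_gc, n_called_gc),
        },
        "co": {
            "n_truth": len(truth_co),
            "n_eligible": n_eligible_co,
            "n_recovered": n_recovered_co,
            "n_called": n_called_co,
            "sensitivity": _ratio(n_recovered_co, n_eligible_co),
            "precision": _ratio(n_precise_co, n_called_co),
            "consistency": _consistency(called_co, exp_co, n_called_co),
        },
        "miss_reasons": miss_reasons,
    }


def _gc_ineligibility_reason(
    tr: TruthEvent,
    informative: Sequence[int],
    pt_site_positions: Optional[Mapping[tuple[str, str], Sequence[int]]],
) -> str:
    inside = [p for p in informative if tr.start <= p <= tr.end]
    if len(inside) < 2:
        if pt_site_positions is not None:
            raw = pt_site_positions.get((tr.parent_of_origin, tr.chrom), ())
            raw_inside = [p for p in raw if tr.start <= p <= tr.end]
            if len(raw_inside) >= 2:
                return "gc_filtered_genotypes"
        return "gc_insufficient_snps"
    if max(inside) - min(inside) + 1 < 20:
        return "gc_short_snp_span"
    return "gc_missing_flank"


def write_truth_tsv(truth: Sequence[TruthEvent], path) -> None:
    """Write ground-truth events as TSV (1-based inclusive coordinates)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["progeny_id", "parent_of_origin", "chrom", "class", "start", "end", "n_snps_covered"]
        )
        for ev in sorted(
            truth, key=lambda e: (e.progeny_id, e.parent_of_origin, e.chrom, e.start)
        ):
            w.writerow(
                [ev.progeny_id, ev.parent_of_origin, ev.chrom, ev.event_class, ev.start, ev.end, ev.n_snps_covered]
            )


def read_truth_tsv(path) -> list[TruthEvent]:
    import csv

    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthEvent(
                    progeny_id=row["progeny_id"],
                    parent_of_origin=row["parent_of_origin"],
                    chrom=row["chrom"],
                    event_class=row["class"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_snps_covered=int(row["n_snps_covered"]),
                )
            )
    return out
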