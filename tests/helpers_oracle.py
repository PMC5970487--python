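"""Independent brute-force oracles used by several test modules.

These deliberately re-derive results with naive, transparent logic
(per-base loops, itertools grouping, explicit conditionals) so that they
share no code path with the implementations they check.
"""

from itertools import groupby


def brute_force_events(
    positions,
    hap1_labels,
    inherited,
    gc_min_bp=20,
    gc_max_bp=2000,
    co_flank_bp=10000,
    gc_min_snps=2,
):
    """Naive reference classification of an inherited label sequence.

    Returns a sorted list of (class, start, end, n_snps) tuples.  The
    homolog at each informative site is 1 where the inherited label equals
    the hap1 label, else 2; maximal runs are grouped with itertools;
    interior runs are classified by explicit rules and junctions between
    two >co_flank_bp runs become crossovers.
    """
    info = [
        (pos, 1 if lab == h1 else 2)
        for pos, h1, lab in zip(positions, hap1_labels, inherited)
        if lab != "missing"
    ]
    runs = []
    for hom, grp in groupby(info, key=lambda t: t[1]):
        grp = list(grp)
        runs.append(
            {
                "hom": hom,
                "start": grp[0][0],
                "end": grp[-1][0],
                "span": grp[-1][0] - grp[0][0] + 1,
                "n": len(grp),
            }
        )
    out = []
    for i, run in enumerate(runs):
        if i == 0 or i == len(runs) - 1:
            continue
        if run["span"] < gc_min_bp or run["n"] < gc_min_snps:
            cls = "ignored_short"
        elif run["span"] < gc_max_bp:
            cls = "gene_conversion"
        else:
            cls = "ambiguous"
        out.append((cls, run["start"], run["end"], run["n"]))
    for left, right in zip(runs, runs[1:]):
        if left["span"] > co_flank_bp and right["span"] > co_flank_bp:
            out.append(("crossover", left["end"], right["start"], 0))
    return sorted(out)


def brute_force_multiplicity(tracts_by_progeny, length):
    """Per-base distinct-progeny coverage counts by explicit looping."""
    cover = [0] * (length + 2)
    for tracts in tracts_by_progeny.values():
        seen = set()
        for start, end in tracts:
            for base in range(start, end + 1):
                seen.add(base)
        for base in seen:
            if base <= length:
                cover[base] += 1
    return cover


def brute_force_merge(blocks, markers):
    """Reference merged haplotype: orient each mapped block independently.

    ``markers`` is a list of (chrom, pos, phase).  Returns the
    (hap1_label, hap2_label, pos) sequence of the merged haplotype, or
    None for blocks left out.  Convention: merged homolog 1 carries 'b'
    at coupling markers, 'a' at repulsion markers.
    """
    marker_at = {(c, p): ph for c, p, ph in markers}
    oriented = []
    for blk in sorted(blocks, key=lambda b: b.span_start):
        votes = []
        for site in blk.sites:
            phase = marker_at.get((blk.chrom, site.pos))
            if phase is None:
                continue
            desired = "b" if phase == "coupling" else "a"
            votes.append(site.ab_label_hap1 != desired)
        if not votes or sum(votes) * 2 == len(votes):
            continue
        swap = sum(votes) * 2 > len(votes)
        for site in blk.sites:
            if swap:
                oriented.append((site.ab_label_hap2, site.ab_label_hap1, site.pos))
            else:
                oriented.append((site.ab_label_hap1, site.ab_label_hap2, site.pos))
    return oriented
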