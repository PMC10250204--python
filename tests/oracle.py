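"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's code paths: the CIGAR oracle walks
the reference one base at a time, and the AISO oracle applies the category
definitions literally with per-base coverage sets and exhaustive loops.
"""

from __future__ import annotations

import re


def brute_cigar(cigar: str, pos: int):
    """Reference-consumption interpreter: returns (blocks, junctions)."""
    covered = set()
    junctions = []
    ref = pos
    for num, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(num)
        if op in "M=XD":
            for i in range(n):
                covered.add(ref + i)
            ref += n
        elif op == "N":
            junctions.append((ref, ref + n))
            ref += n
        # I, S, H, P consume no reference
    blocks = []
    for base in sorted(covered):
        if blocks and base == blocks[-1][1]:
            blocks[-1][1] = base + 1
        else:
            blocks.append([base, base + 1])
    return [tuple(b) for b in blocks], junctions


def _near(a: int, candidates, tol: int) -> bool:
    for c in candidates:
        if -tol <= a - c <= tol:
            return True
    return False


def brute_regions(entity):
    """Naive effective-region computation (None when a neighbor is missing)."""
    lo = min(entity.starts)
    hi = max(entity.ends)
    if entity.strand == "+":
        ups = [c for c in entity.upstream_neighbor_ends if c <= lo]
        dns = [c for c in entity.downstream_neighbor_starts if c >= hi]
        if not ups or not dns:
            return None
        up_full = (max(ups), lo)
        do_full = (hi, min(dns))
    else:
        ups = [c for c in entity.upstream_neighbor_ends if c >= hi]
        dns = [c for c in entity.downstream_neighbor_starts if c <= lo]
        if not ups or not dns:
            return None
        up_full = (hi, min(ups))
        do_full = (max(dns), lo)
    len_up = up_full[1] - up_full[0]
    len_do = do_full[1] - do_full[0]
    if len_up <= 0 or len_do <= 0:
        return None
    eff = min(len_up, len_do)
    if entity.strand == "+":
        up_region = (lo - eff, lo)
        do_region = (hi, hi + eff)
    else:
        up_region = (hi, hi + eff)
        do_region = (lo - eff, lo)
    return {"up": up_region, "do": do_region, "up_full": up_full, "do_full": do_full}


def _junction_match(frag, entity, side, tol):
    plus = entity.strand == "+"
    if side == "up":
        donors = entity.upstream_neighbor_ends if plus else entity.ends
        acceptors = entity.starts if plus else entity.upstream_neighbor_ends
    else:
        donors = entity.ends if plus else entity.downstream_neighbor_starts
        acceptors = entity.downstream_neighbor_starts if plus else entity.starts
    for d, a in frag.junctions:
        if _near(d, donors, tol) and _near(a, acceptors, tol):
            return True
    return False


def _best_block_overlap(frag, region):
    """Largest number of bases a single block has inside the region."""
    best = 0
    for s, e in frag.blocks:
        inside = sum(1 for b in range(s, e) if region[0] <= b < region[1])
        best = max(best, inside)
    return best


def _spans(frag, boundary, min_overlap):
    for s, e in frag.blocks:
        left = len([b for b in range(s, e) if b < boundary])
        right = len([b for b in range(s, e) if b >= boundary])
        # only contiguous coverage of the boundary counts
        if left >= min_overlap and right >= min_overlap and s < boundary < e:
            return True
    return False


def brute_classify(frag, entity, tol=3, min_overlap=6):
    """Literal application of the category definitions; returns a dict of increments."""
    out = {k: 0 for k in ("upfi", "dofi", "bus", "bos", "skip", "inup", "indo",
                          "ei_up", "ei_do", "nb_up", "nb_do", "discarded")}
    regions = brute_regions(entity)
    if regions is None:
        return out
    ju = _junction_match(frag, entity, "up", tol)
    jd = _junction_match(frag, entity, "do", tol)
    iu = _best_block_overlap(frag, regions["up"]) >= min_overlap
    idn = _best_block_overlap(frag, regions["do"]) >= min_overlap
    if (ju and iu) or (jd and idn):
        out["discarded"] = 1
        return out
    if ju and idn:
        out["upfi"] = 1
    elif iu and jd:
        out["dofi"] = 1
    elif ju and jd:
        out["bos"] = 1
    elif iu and idn:
        out["bus"] = 1
    if ju:
        out["inup"] = 1
    if jd:
        out["indo"] = 1

    plus = entity.strand == "+"
    skip_donors = entity.upstream_neighbor_ends if plus else entity.downstream_neighbor_starts
    skip_acceptors = entity.downstream_neighbor_starts if plus else entity.upstream_neighbor_ends
    for d, a in frag.junctions:
        if _near(d, skip_donors, tol) and _near(a, skip_acceptors, tol):
            out["skip"] = 1
            break

    if plus:
        nb_up_b, ei_up_b = regions["up_full"]
        ei_do_b, nb_do_b = regions["do_full"]
    else:
        ei_up_b, nb_up_b = regions["up_full"]
        nb_do_b, ei_do_b = regions["do_full"]
    out["ei_up"] = int(_spans(frag, ei_up_b, min_overlap))
    out["nb_up"] = int(_spans(frag, nb_up_b, min_overlap))
    out["ei_do"] = int(_spans(frag, ei_do_b, min_overlap))
    out["nb_do"] = int(_spans(frag, nb_do_b, min_overlap))
    return out


def brute_count(entity, fragments, tol=3, min_overlap=6):
    total = {k: 0 for k in ("upfi", "dofi", "bus", "bos", "skip", "inup", "indo",
                            "ei_up", "ei_do", "nb_up", "nb_do", "discarded")}
    for frag in fragments:
        if frag.chrom != entity.chrom or not frag.blocks:
            continue
        for key, val in brute_classify(frag, entity, tol, min_overlap).items():
            total[key] += val
    return total
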