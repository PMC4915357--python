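"""Discrete-generation Wright-Fisher tract kernel.

The population is 2N haplotypes; a haplotype is an ordered list of ancestry
tracts over a single concatenated genetic axis [0, G) cM (chromosome
boundaries are supplied so that chromosomes assort independently).  Each
generation every offspring haplotype is produced by a meiosis of one parent
individual drawn uniformly with replacement: crossover positions are Poisson
(G/100 expected per meiosis, i.e. one per Morgan) and uniform on the genetic
map, and the copied tracts inherit their ancestry labels.  Migrant
individuals, when an admixture event falls on the generation being formed,
enter as unadmixed haplotype pairs.

Tracts are stored run-length compressed (adjacent equal labels merged), so
the arrays hold ancestry junctions only.  Randomness is drawn in bulk per
generation; children are *built* in parent-sorted order (for near-sequential
access to the parent tract arrays) and their variable-length tract blocks are
permuted back to child order afterwards, leaving the i.i.d. uniform parent
assignment untouched.  The kernel seeds numba's own MT19937 stream, so a
fixed seed gives identical output.
"""

import numpy as np
from numba import njit

__all__ = ["evolve_population"]


@njit(cache=True)
def evolve_population(seed, n_dip, g0, chrom_bounds, founding_n_a, src_a, src_b,
                      ev_gens, ev_srcs, ev_ndip):
    """Evolve a founding population g0 generations to the present.

    chrom_bounds: float64 chromosome boundaries in cM, from 0 to the total
    genome length G.  ev_gens[j]: generations before present at which migrant
    event j applies (strictly less than g0); ev_ndip[j] migrant diploids of
    ancestry ev_srcs[j] replace the first individual slots of the generation
    formed at that time.

    Returns (ends, labels, offsets) for the 2N present-day haplotypes.
    """
    np.random.seed(seed)
    n_hap = 2 * n_dip
    G = chrom_bounds[-1]
    n_chr = chrom_bounds.shape[0] - 1
    lam = G / 100.0  # expected crossovers per meiosis (1 per Morgan)

    # founding generation: unadmixed individuals, the first founding_n_a of
    # ancestry src_a, the rest src_b
    ends = np.empty(n_hap, np.float64)
    labels = np.empty(n_hap, np.int8)
    offs = np.empty(n_hap + 1, np.int64)
    for i in range(n_hap):
        offs[i] = i
        ends[i] = G
        labels[i] = src_a if (i // 2) < founding_n_a else src_b
    offs[n_hap] = n_hap
    total = n_hap

    for t in range(g0 - 1, -1, -1):
        n_mig = 0
        src = np.int8(0)
        for e in range(ev_gens.shape[0]):
            if ev_gens[e] == t:
                n_mig = ev_ndip[e]
                src = ev_srcs[e]
        n_child = n_hap - 2 * n_mig

        # bulk randomness for the whole generation
        parents = np.random.randint(0, n_dip, n_child)
        order = np.argsort(parents, kind="mergesort")
        n_cx = np.random.poisson(lam, n_child)
        cx_off = np.empty(n_child + 1, np.int64)
        cx_off[0] = 0
        for i in range(n_child):
            cx_off[i + 1] = cx_off[i] + n_cx[i]
        cx_all = np.random.uniform(0.0, G, cx_off[n_child])
        for i in range(n_child):
            cx_all[cx_off[i]:cx_off[i + 1]].sort()
        assort = np.random.randint(0, 2, n_child * n_chr)

        cap = 2 * total + 16 * n_hap
        b_ends = np.empty(cap, np.float64)
        b_labels = np.empty(cap, np.int8)
        b_start = np.empty(n_child, np.int64)  # block start per child
        b_len = np.empty(n_child, np.int64)
        bt = 0
        for oi in range(n_child):
            ch = order[oi]
            p = parents[ch]
            c0 = cx_off[ch]
            c1 = cx_off[ch + 1]
            which = assort[ch * n_chr]
            ci = c0
            last_label = np.int8(-100)
            first_of_child = True
            # worst case this meiosis appends (parent tracts + segment count)
            need = bt + (offs[2 * p + 2] - offs[2 * p]) + (c1 - c0) + n_chr + 2
            if need > cap:
                new_cap = cap
                while new_cap < need + total:
                    new_cap *= 2
                ne = np.empty(new_cap, np.float64)
                nl = np.empty(new_cap, np.int8)
                ne[:bt] = b_ends[:bt]
                nl[:bt] = b_labels[:bt]
                b_ends = ne
                b_labels = nl
                cap = new_cap
            b_start[ch] = bt
            for c in range(n_chr):
                c_end = chrom_bounds[c + 1]
                if c > 0:
                    which ^= assort[ch * n_chr + c]
                pos = chrom_bounds[c]
                while pos < c_end:
                    seg_end = c_end
                    crossed = False
                    if ci < c1 and cx_all[ci] < c_end:
                        seg_end = cx_all[ci]
                        crossed = True
                    if seg_end > pos:
                        # copy [pos, seg_end) from the active parent haplotype
                        h = 2 * p + which
                        lo = offs[h]
                        hi = offs[h + 1]
                        j = lo + np.searchsorted(ends[lo:hi], pos, side="right")
                        cur = pos
                        while cur < seg_end:
                            e_j = ends[j]
                            lab = labels[j]
                            piece_end = e_j if e_j < seg_end else seg_end
                            if (not first_of_child) and lab == last_label:
                                b_ends[bt - 1] = piece_end
                            else:
                                b_ends[bt] = piece_end
                                b_labels[bt] = lab
                                bt += 1
                                last_label = lab
                                first_of_child = False
                            cur = piece_end
                            j += 1
                    if crossed:
                        ci += 1
                        which ^= 1
                    pos = seg_end
            b_len[ch] = bt - b_start[ch]

        # assemble the new generation in child index order
        ot = 2 * n_mig + 0
        total_new = 2 * n_mig
        for ch in range(n_child):
            total_new += b_len[ch]
        o_ends = np.empty(total_new, np.float64)
        o_labels = np.empty(total_new, np.int8)
        o_offs = np.empty(n_hap + 1, np.int64)
        for i in range(2 * n_mig):
            o_offs[i] = i
            o_ends[i] = G
            o_labels[i] = src
        pos_out = 2 * n_mig
        for ch in range(n_child):
            o_offs[2 * n_mig + ch] = pos_out
            s = b_start[ch]
            L = b_len[ch]
            o_ends[pos_out:pos_out + L] = b_ends[s:s + L]
            o_labels[pos_out:pos_out + L] = b_labels[s:s + L]
            pos_out += L
        o_offs[n_hap] = pos_out
        ends = o_ends
        labels = o_labels
        offs = o_offs
        total = pos_out
    return ends, labels, offs
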