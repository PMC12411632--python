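"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately written in a slow, literal style, without sharing code with the
package implementation, so they can arbitrate correctness.
"""

from __future__ import annotations

import itertools


def oracle_clonotype_calls(contigs, mode="genes_plus_cdr3aa", require_productive=True):
    """Literal transcription of the four contig rules; returns {barcode: key}."""
    # rule 1
    kept = [c for c in contigs
            if c.high_confidence and (c.productive or not require_productive)]
    out = {}
    for bc in {c.barcode for c in kept}:
        mine = [c for c in kept if c.barcode == bc]
        # rule 2: per chain, max UMI; ties by (cdr3_nt, v_gene)
        chosen = {}
        for chain in ("TRA", "TRB"):
            cands = [c for c in mine if c.chain == chain]
            if not cands:
                continue
            best = min(cands, key=lambda c: (-c.umis, c.cdr3_nt, c.v_gene,
                                             c.j_gene, c.d_gene, c.cdr3_aa))
            chosen[chain] = best
        # rule 3
        if "TRA" not in chosen or "TRB" not in chosen:
            continue
        a, b = chosen["TRA"], chosen["TRB"]
        # rule 4
        if mode == "genes_only":
            key = "TRA:" + ".".join((a.v_gene, a.j_gene)) + \
                  "|TRB:" + ".".join((b.v_gene, b.d_gene, b.j_gene))
        else:
            key = "TRA:" + ".".join((a.v_gene, a.j_gene, a.cdr3_aa)) + \
                  "|TRB:" + ".".join((b.v_gene, b.d_gene, b.j_gene, b.cdr3_aa))
        out[bc] = key
    return out


def oracle_expansion_status(n_bf, n_fl, N_bf, N_fl, tau=2.0, m=3, proportional=True):
    """Truth table of the expansion rule for one clonotype."""
    if n_bf == 0 and n_fl == 0:
        return "not_expanded"
    if n_bf == 0:
        # absent at baseline, present at flare
        if n_fl >= m:
            return "expanded_de_novo"
        return "excluded_min_cells"
    grows = n_fl >= tau * n_bf
    if proportional:
        grows = grows and (n_fl / N_fl) > (n_bf / N_bf)
    if not grows:
        return "not_expanded"
    if n_fl < m:
        return "excluded_min_cells"
    return "expanded_fold"


def oracle_bh(pvalues):
    """Step-up BH by direct definition: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adj = [None] * m
    running_min = float("inf")
    for pos in range(m - 1, -1, -1):
        i = indexed[pos]
        running_min = min(running_min, m * pvalues[i] / (pos + 1))
        adj[i] = min(running_min, 1.0)
    return adj
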