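"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def oracle_match(ref_bits, tgt_bits):
    """O(N^2) two-pass nearest-neighbour + cross-check matcher.

    Plain loops, explicit tie-breaking toward the lowest index; independent
    of the packed-bit implementation it validates.
    """
    nr, nt = len(ref_bits), len(tgt_bits)
    dist = [[int(np.count_nonzero(ref_bits[i] != tgt_bits[j]))
             for j in range(nt)] for i in range(nr)]
    fwd = [min(range(nt), key=lambda j: (dist[i][j], j)) for i in range(nr)]
    bwd = [min(range(nr), key=lambda i: (dist[i][j], i)) for j in range(nt)]
    return sorted((i, fwd[i], dist[i][fwd[i]])
                  for i in range(nr) if bwd[fwd[i]] == i)
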