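"""Score a toy lncRNA-mRNA candidate with the shared-miRNA statistics.

A universe of 24 miRNAs; the mRNA is paired with 10 of them, the lncRNA
with 7, and 4 are shared. The ceRNA score (4/7) is the fraction of the
lncRNA's partners shared with the mRNA; the hypergeometric tail p is the
chance of sharing at least 4 partners under random pairing — small values
mean the overlap is unlikely by chance.
"""

from itertools import combinations

import cerna_triad as ct

M_T, m_p, m_n, m_c = 24, 10, 7, 4
score = ct.cerna_score(m_c, m_n)
pval = ct.hypergeom_pvalue(M_T, m_p, m_n, m_c)
print(f"universe M_T={M_T}, mRNA partners m_p={m_p}, lncRNA partners m_n={m_n}, shared m_c={m_c}")
print(f"ceRNA score = m_c/m_n = {score:.4f}")
print(f"hypergeometric tail p = {pval:.6f}")

# independent check by enumerating every 10-subset of the universe
lnc_set = set(range(m_n))
hits = sum(1 for s in combinations(range(M_T), m_p) if len(lnc_set & set(s)) >= m_c)
total = len(list(combinations(range(M_T), m_p)))
print(f"enumeration: {hits}/{total} subsets overlap in >= {m_c} -> {hits / total:.6f}")
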