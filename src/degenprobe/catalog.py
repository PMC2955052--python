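"""Reference probe catalog: the PAH-degradation explorative probe set.

Sixteen 23-mer degenerate probes (two regions, A and B, per gene)
targeting eight genes of the polycyclic-aromatic-hydrocarbon degradation
pathway of *Sphingomonas paucimobilis* EPA505: the ring-hydroxylating
dioxygenase subunits (phnA1a, phnA2a), oxygenase subunits (ahdA1c,
ahdA2c), dihydrodiol dehydrogenase (bphB), biphenyl-2,3-diol
1,2-dioxygenase (bphC), ferredoxin (bphA3) and ferredoxin reductase
(ahdA4).  They were designed with the two standard 24-mer strategies
(degeneracy 129 / inosine 25%, and degeneracy 258 / inosine 9%) followed
by last-base trimming, and serve as worked-example input and regression
data for the expansion arithmetic.

Note: the published variant count for bphB_MD_B (384) is inconsistent
with its sequence, whose cartesian expansion yields 1,536; the catalog
carries the sequence as published.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CatalogProbe:
    gene: str
    name: str
    seq: str
    start_nt: int  # 1-based inclusive on the reference gene CDS
    end_nt: int


PROBE_CATALOG: tuple[CatalogProbe, ...] = (
    CatalogProbe("phnA1a", "phnA1a_MD_A", "GTITGYAAYTAYCAYGGITGGGT", 294, 316),
    CatalogProbe("phnA1a", "phnA1a_MD_B", "CAYGARATHGARGTITGGACITA", 957, 979),
    CatalogProbe("phnA2a", "phnA2a_MD_A", "GARGAYATHCAYTAYTGGATGCC", 123, 145),
    CatalogProbe("phnA2a", "phnA2a_MD_B", "GGICARGTITGGATGGARGAYCC", 261, 284),
    CatalogProbe("ahdA1c", "ahdA1c_MD_A", "GARTGYGTITAYCAYCARTGGGC", 318, 340),
    CatalogProbe("ahdA1c", "ahdA1c_MD_B", "GAYGCIGCIGAYAARCARGCITA", 771, 793),
    CatalogProbe("ahdA2c", "ahdA2c_MD_A", "GAYGAYMGIYTIGARGARTGGCC", 81, 103),
    CatalogProbe("ahdA2c", "ahdA2c_MD_B", "ATHGAYACIATGATGGTIMGICC", 459, 481),
    CatalogProbe("bphB", "bphB_MD_A", "AAYGTIGGIATHTGGGAYTWYAT", 261, 283),
    CatalogProbe("bphB", "bphB_MD_B", "AAYBTIAARGGITAYTTYTTYGG", 348, 370),
    CatalogProbe("bphC", "bphC_MD_A", "CCITAYTTYATGCAYTGYAAYGA", 558, 580),
    CatalogProbe("bphC", "bphC_MD_B", "TGGYTITGGGARTTYGGITGGGG", 777, 799),
    CatalogProbe("bphA3", "bphA3_MD_A", "ATHATHGARTGYCCITTYCAYGG", 180, 202),
    CatalogProbe("bphA3", "bphA3_MD_B", "ATHGAIGAYGGITGGGTITGYAT", 279, 302),
    CatalogProbe("ahdA4", "ahdA4_MD_A", "GCIAAYGTICCIGAYAAYTTYTT", 159, 181),
    CatalogProbe("ahdA4", "ahdA4_MD_B", "CARGARACITAYCARAAYGCIGC", 867, 889),
)

BY_NAME: dict[str, CatalogProbe] = {p.name: p for p in PROBE_CATALOG}
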