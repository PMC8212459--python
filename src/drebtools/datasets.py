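"""Published reference tables bundled for reproduction checks.

Two small tables from the genome-wide *Saccharum spontaneum* DREB survey:
the chromosomal coordinates of the published tandem-duplication clusters,
and the synonymous-rate (Ks) estimates with the divergence times reported
for sorghum-sugarcane DREB1 ortholog pairs. These are printed inputs, not
computed outputs; the genome itself is an optional external input that the
synthetic-data module stands in for.
"""

from __future__ import annotations

import pandas as pd

from .records import GeneModel

# (cluster, gene name, chromosome, start, end)
_TANDEM_ROWS = [
    (1, "SsDREB1C-2", "Chr2D", 22_208_944, 22_209_639),
    (1, "SsDREB1I", "Chr2D", 22_226_936, 22_227_607),
    (2, "SsDREB1B-3", "Chr2D", 22_092_288, 22_093_103),
    (2, "SsDREB1G", "Chr2D", 22_107_221, 22_108_036),
    (2, "SsDREB1F-2", "Chr2D", 22_113_187, 22_113_903),
    (2, "SsDREB1H", "Chr2D", 22_117_638, 22_118_345),
    (2, "SsDREB1A-4", "Chr2D", 22_126_308, 22_127_015),
    (3, "SsDREB1B-2", "Chr2B", 26_564_597, 26_565_409),
    (3, "SsDREB1C-1", "Chr2B", 26_597_272, 26_598_093),
    (3, "SsDREB1D", "Chr2B", 26_612_975, 26_613_670),
    (4, "SsDREB1A-3", "Chr2C", 30_543_015, 30_543_701),
    (4, "SsDREB1E", "Chr2C", 30_554_216, 30_554_923),
]

# (ortholog pair, Ks, published divergence time in Mya)
_ORTHOLOG_KS_ROWS = [
    ("SbDREB1A-SsDREB1C-2", 0.079, 6.487),
    ("SbDREB1A-SsDREB1D", 0.079, 6.496),
    ("SbDREB1A-SsDREB1I", 0.096, 7.841),
    ("SbDREB1D-SsDREB1E", 0.133, 10.917),
    ("SbDREB1D-SsDREB1H", 0.140, 11.496),
    ("SbDREB1A-SsDREB1C-1", 0.170, 13.902),
    ("SbDREB1B-SsDREB1B-2", 0.180, 14.747),
    ("SbDREB1B-SsDREB1B-1", 0.183, 15.038),
    ("SbDREB1B-SsDREB1G", 0.191, 15.686),
    ("SbDREB1E-SsDREB1A-4", 0.213, 17.444),
    ("SbDREB1E-SsDREB1A-2", 0.230, 18.874),
]


def tandem_reference_table() -> pd.DataFrame:
    """Published tandem-cluster coordinates (12 DREB1 alleles, 4 clusters
    on chromosomes 2B/2C/2D)."""
    return pd.DataFrame(
        _TANDEM_ROWS, columns=["cluster", "gene", "chromosome", "start", "end"]
    )


def tandem_reference_genes() -> list[GeneModel]:
    return [
        GeneModel(gene, chrom, start, end, "unknown")
        for _c, gene, chrom, start, end in _TANDEM_ROWS
    ]


def tandem_reference_edges():
    """Within-cluster homology edges implied by the published clustering
    (identity 1.0 placeholders; only membership matters)."""
    from .duplication import HomologyEdge

    edges = []
    for i, (ca, ga, *_rest) in enumerate(_TANDEM_ROWS):
        for cb, gb, *_rest2 in _TANDEM_ROWS[i + 1 :]:
            if ca == cb:
                edges.append(HomologyEdge(ga, gb, 1.0, "provided"))
    return edges


def ortholog_ks_table() -> pd.DataFrame:
    """Published Ks values and divergence times (Mya) for sorghum-sugarcane
    DREB1 ortholog pairs."""
    return pd.DataFrame(
        _ORTHOLOG_KS_ROWS, columns=["pair", "ks", "t_mya_published"]
    )
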