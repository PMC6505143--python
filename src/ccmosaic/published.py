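"""Published characterization values for the six CC strains released by
the UNC Systems Genetics Core (CC078/TauUnc .. CC083/Unc).

These printed per-strain values are *inputs* to the summary routines
(population averages, deletion size bookkeeping); the pipeline itself is
exercised on synthetic data, since the underlying genotype and sequence
archives are external resources.
"""

from __future__ import annotations

import pandas as pd

from .founders import FOUNDER_IDS
from .delscan import tile_size_kb

NEW_STRAINS = (
    "CC078/TauUnc",
    "CC079/TauUnc",
    "CC080/TauUnc",
    "CC081/Unc",
    "CC082/Unc",
    "CC083/Unc",
)

#: residual heterozygosity (%) per strain: in the MRCAs, in the single
#: sequenced mouse, and in the three colony-survey array genotypes
MRCA_HET_PCT = pd.DataFrame(
    {
        "mrca": [14.29996, 6.766071, 22.18861, 21.91887, 22.76935, 31.48258],
        "sequenced_sample": [1.7, 4.5, 3.77, 3.7, 5.0, 15.4],
        "three_genotyped_mice": [5.52, 8.62, 17.11, 18.81, 18.84, 28.87],
    },
    index=pd.Index(NEW_STRAINS, name="strain"),
)

#: founder-haplotype frequency per sequenced sample (rows sum to ~1)
FOUNDER_FREQUENCIES = pd.DataFrame(
    [
        [0.176, 0.166, 0.142, 0.113, 0.046, 0.098, 0.136, 0.123],
        [0.199, 0.147, 0.130, 0.086, 0.109, 0.157, 0.135, 0.038],
        [0.163, 0.223, 0.151, 0.059, 0.182, 0.055, 0.027, 0.140],
        [0.089, 0.148, 0.181, 0.154, 0.153, 0.071, 0.101, 0.096],
        [0.148, 0.101, 0.062, 0.107, 0.150, 0.177, 0.099, 0.149],
        [0.177, 0.166, 0.142, 0.110, 0.046, 0.098, 0.136, 0.123],
    ],
    index=pd.Index(NEW_STRAINS, name="strain"),
    columns=list(FOUNDER_IDS),
)

#: strain-private de novo deletions: 45-mer tile interval, resolved
#: breakpoints, printed size, junction-spanning reads, haplotype label
DENOVO_DELETIONS = pd.DataFrame(
    [
        ("CC079/TauUnc", "8", 102931561, 102947356, 102931583, 102947323, 15.795, None, "129S1/SvImJ"),
        ("CC079/TauUnc", "X", 11600371, 11620171, 11600372, 11620112, 19.8, 11, "PWK/PhJ"),
        ("CC079/TauUnc", "2", 129264616, 129265201, 129264705, 129265185, 0.585, 37, "PWK/PhJ"),
        ("CC081/Unc", "10", 56858446, 56862406, 56858470, 56862407, 3.96, 40, "C57BL/6J"),
    ],
    columns=[
        "strain", "chrom", "tile_start", "tile_end", "resolved_start",
        "resolved_end", "size_kb", "spanning_reads", "haplotype",
    ],
)


def average_mrca_heterozygosity(values=None, decimals: int = 1) -> float:
    """Average residual heterozygosity (%) across strains, rounded to the
    reporting precision. Defaults to the six released strains' MRCA values."""
    if values is None:
        values = MRCA_HET_PCT["mrca"]
    return round(float(pd.Series(values).mean()), decimals)


def average_founder_frequency(founder: str, table: pd.DataFrame | None = None,
                              decimals: int = 3) -> float:
    """Across-strain average frequency of one founder haplotype."""
    table = FOUNDER_FREQUENCIES if table is None else table
    return round(float(table[founder].mean()), decimals)


def deletion_sizes_kb(table: pd.DataFrame | None = None) -> pd.Series:
    """Recompute each deletion's size from its tile coordinates using the
    (tile_end - tile_start)/1000 convention."""
    table = DENOVO_DELETIONS if table is None else table
    return pd.Series(
        [tile_size_kb(s, e) for s, e in zip(table["tile_start"], table["tile_end"])],
        index=table.index,
        name="size_kb",
    )
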