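"""Synthetic genome model: chromosome arms and driver-gene loci.

A simplified hg19-like autosome set: 22 chromosomes, each with a 40 Mb
p arm and a 60 Mb q arm.  Driver genes frequently altered in gastric
cancer are placed at fixed loci so that simulated focal events and
gene-level copy-number calls share a coordinate frame.  All intervals
here are 0-based half-open, matching the package's internal convention.
"""

from __future__ import annotations

import pandas as pd

P_ARM_LEN = 40_000_000
Q_ARM_LEN = 60_000_000
CHROM_LEN = P_ARM_LEN + Q_ARM_LEN
CHROMOSOMES = [str(c) for c in range(1, 23)]

GENOME_LEN = CHROM_LEN * len(CHROMOSOMES)

#: consensus gastric-cancer driver genes used by the simulator and the
#: bundled driver list; loci are synthetic but fixed.
DRIVER_GENES = {
    # gene: (chrom, start0, end0)
    "TP53": ("17", 7_500_000, 7_520_000),
    "RHOA": ("3", 49_400_000, 49_450_000),
    "CDH1": ("16", 68_770_000, 68_870_000),
    "KRAS": ("12", 25_350_000, 25_400_000),
    "MYC": ("8", 62_700_000, 62_710_000),
    "EGFR": ("7", 55_000_000, 55_200_000),
    "ERBB2": ("17", 57_800_000, 57_840_000),
    "PIK3CA": ("3", 78_900_000, 78_990_000),
    "CCNE1": ("19", 30_300_000, 30_310_000),
    "FGFR2": ("10", 83_500_000, 83_620_000),
    "MET": ("7", 76_200_000, 76_330_000),
    "ARID1A": ("1", 27_020_000, 27_110_000),
}


#: arm-level alterations recurrent in chromosomally unstable (CIN)
#: gastric tumors; +1 = recurrent gain, -1 = recurrent loss.  Shared by
#: the simulator and the CIN reference panel so that CIN profiles carry
#: a common directional signal, as in real cohorts.
RECURRENT_ARM_EVENTS = {
    "1q": +1, "3q": +1, "5p": +1, "6p": +1, "7p": +1, "7q": +1,
    "8q": +1, "13q": +1, "20p": +1, "20q": +1,
    "4q": -1, "9p": -1, "17p": -1, "18q": -1, "21q": -1,
}


def default_arms() -> pd.DataFrame:
    """Arm definition table: chrom, arm (p/q), start, end (0-based half-open)."""
    rows = []
    for chrom in CHROMOSOMES:
        rows.append({"chrom": chrom, "arm": "p", "start": 0, "end": P_ARM_LEN})
        rows.append({"chrom": chrom, "arm": "q", "start": P_ARM_LEN, "end": CHROM_LEN})
    return pd.DataFrame(rows)


def default_gene_intervals() -> pd.DataFrame:
    """Driver gene interval table: gene, chrom, start, end."""
    rows = [
        {"gene": g, "chrom": c, "start": s, "end": e}
        for g, (c, s, e) in DRIVER_GENES.items()
    ]
    return pd.DataFrame(rows)


def default_driver_list() -> list[str]:
    return list(DRIVER_GENES)
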