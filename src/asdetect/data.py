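"""Bundled worked-example dataset.

A small published-style table of budding-yeast sense genes whose
expression changed in a SET2-deletion strain together with the
upregulated antisense transcription units overlapping them: one row per
(gene, antisense unit), with the log2 fold change (mutant over WT) and
p-value for both the sense gene and the antisense unit. Antisense units
are named by their genomic interval (chrom_start_end, 1-based
inclusive). Note *CLB6* carries two distinct antisense units, so gene-level
summaries must deduplicate.

Used by the README worked example and the cross-tabulation demo: running
these rows through the fold-change/p classifier and the sense-antisense
cross-tabulation recovers 6 distinct genes upregulated and 8 distinct
genes downregulated alongside an upregulated antisense unit.
"""

from __future__ import annotations

import io

import pandas as pd

EXAMPLE_PAIRS_TSV = """\
gene_id\tsense_log2fc\tsense_pvalue\tantisense_id\tantisense_log2fc\tantisense_pvalue
FIG2\t1.22\t6.47e-34\tchrIII_268287_269650\t6.08\t1.25e-54
FLO10\t1.26\t2.11e-22\tchrXI_646150_649088\t4.35\t4.98e-191
GTT2\t1.08\t1.94e-17\tchrXII_21160_21867\t2.33\t1.90e-14
HEF3\t1.37\t1.66e-35\tchrXIV_607466_608421\t3.70\t6.04e-36
SFL1\t1.03\t2.06e-14\tchrXV_587861_589241\t2.19\t1.84e-24
PCA1\t1.48\t6.05e-51\tchrII_792527_796498\t4.41\t1.33e-140
AVT2\t-1.03\t2.63e-14\tchrV_30251_31501\t2.97\t2.74e-30
ADE5,7\t-1.23\t5.40e-37\tchrVII_56171_57183\t1.96\t3.14e-10
CLB6\t-1.04\t6.77e-05\tchrVII_706126_706667\t2.60\t8.40e-12
CLB6\t-1.04\t6.77e-05\tchrVII_705368_706105\t2.50\t6.52e-15
YJL213W\t-1.20\t1.67e-28\tchrX_31954_33105\t2.25\t8.46e-12
SRY1\t-1.91\t1.18e-67\tchrXI_17659_18490\t1.87\t1.22e-14
YLR124W\t-3.34\t7.80e-07\tchrXII_391411_393246\t1.60\t5.78e-27
HXT2\t-1.07\t1.81e-08\tchrXIII_288228_289458\t1.98\t2.45e-14
INP2\t-1.17\t4.04e-17\tchrXIII_584350_585354\t2.83\t6.67e-25
"""


def example_pairs() -> pd.DataFrame:
    """The bundled sense/antisense pair table as a DataFrame."""
    return pd.read_csv(io.StringIO(EXAMPLE_PAIRS_TSV), sep="\t")


def example_de_tables():
    """Expand the bundled table into the package's native objects.

    Returns ``(sense_de, antisense_de, pairs)``: two DE tables (indexed by
    gene / antisense-unit id, with log2fc, pvalue, qvalue and a status
    assigned by the twofold / p<0.05 classifier) and the unit->gene pair
    list, ready for :func:`asdetect.sets.crosstab_sense_antisense`.
    """
    from asdetect.core import SenseAntisensePair
    from asdetect.quant import classify_de

    df = example_pairs()

    sense = (
        df[["gene_id", "sense_log2fc", "sense_pvalue"]]
        .drop_duplicates("gene_id")
        .rename(columns={"sense_log2fc": "log2fc", "sense_pvalue": "pvalue"})
        .set_index("gene_id")
    )
    antisense = (
        df[["antisense_id", "antisense_log2fc", "antisense_pvalue"]]
        .drop_duplicates("antisense_id")
        .rename(columns={"antisense_log2fc": "log2fc", "antisense_pvalue": "pvalue"})
        .set_index("antisense_id")
    )
    for table in (sense, antisense):
        table["qvalue"] = table["pvalue"]
        table["status"] = [
            classify_de(fc, p) for fc, p in zip(table["log2fc"], table["pvalue"])
        ]
    pairs = [
        SenseAntisensePair(feature_id=r.antisense_id, gene_id=r.gene_id, overlap_bp=1)
        for r in df.itertuples()
    ]
    return sense, antisense, pairs
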