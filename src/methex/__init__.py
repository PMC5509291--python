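"""methex: integrated RRBS methylome / RNA-seq transcriptome analysis of
placental gestational age.

Differential methylation is called on merged CpG regions, promoters and
gene bodies with exact small-sample statistics; differential expression on
floored RPKM; and the two are integrated through context-stratified
expression-bin curves and sign-concordance tests.
"""

from importlib import resources

import pandas as pd

from .annotation import (
    AnnotatedInterval,
    CgiContext,
    Feature,
    GeneModel,
    ImprintStatus,
    assign_to_feature,
    cgi_flag,
    exon_intron_partition,
    gene_body_interval,
    promoter_interval,
)
from .dmr import Direction, DmrResult, call_gene_body_dmr, call_promoter_dmr, summarize_dmrs
from .expression import (
    DeDirection,
    DeResult,
    ExpressionTable,
    call_de,
    call_de_all,
    filter_low_expression,
    floor_group_average,
    imprinted_overlay,
    rpkm,
    summarize_de,
)
from .integration import (
    BinCurve,
    Concordance,
    ConcordanceRecord,
    bin_genes_by_expression,
    bin_methylation_curve,
    compare_baseline_expression,
    concordance_table,
    concordance_test,
    normalize_luciferase,
)
from .methylome import (
    CpGCall,
    FilteredCpGMatrix,
    Group,
    MergedRegion,
    MethylationCallSet,
    filter_sites,
    merge_regions,
    methylation_histograms,
    read_coverage_file,
    sample_mean_methylation,
    site_group_mean,
)
from .pipeline import RunConfig
from .simulate import SimConfig, simulate_counts, simulate_genome, simulate_methylome, truth_table
from .stats import TestResult, benjamini_hochberg, exact_binomial_two_sided, exact_mann_whitney

__version__ = "0.1.0"


def load_reference_table(name: str) -> pd.DataFrame:
    """Bundled reference tables from a placental gestational-age study.

    ``imprinted_expression``: group-average RPKM and parental status for the
    11 differentially expressed imprinted genes (printed log2 column kept
    for cross-checking).  ``promoter_concordance``: the 25 genes significant
    in both the promoter-methylation and expression analyses, with their
    methylation change (3T-1T, percentage points) and expression log2(3T/1T).
    """
    fname = {"imprinted_expression": "imprinted_expression.tsv",
             "promoter_concordance": "promoter_concordance.tsv"}[name]
    with resources.files("methex.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")
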