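"""Bundled reference fixtures (small transcribed TSV tables).

These are curated reference tables from a zebrafish hepatocellular
carcinoma (HCC) MeDIP-chip study: promoter CGI regions with altered
methylation, the gene-level concordance of expression and methylation
changes, and the expression-comparison funnel counts. Coordinates in the
CGI table are 1-based inclusive as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("medip_tile.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_hcc_cgi_regions(deduplicate: bool = False) -> pd.DataFrame:
    """Differentially methylated promoter CGI regions in zebrafish HCC.

    Columns: gene_name, gene_id, chrom, cgi_start, cgi_end (1-based
    inclusive), direction (hypo/hyper), category. One row is printed
    twice in the source table under two categories; pass
    ``deduplicate=True`` to drop the repeat.
    """
    df = _load("zebrafish_hcc_cgi_regions.tsv")
    if deduplicate:
        df = df.drop_duplicates(subset=["gene_id", "cgi_start", "cgi_end"]).reset_index(drop=True)
    return df


def load_hcc_concordance() -> pd.DataFrame:
    """Genes with both significant expression and methylation changes.

    Columns: gene_name, symbol, chrom, expression (up/down), methylation
    (up/down), gene_id. Genes whose probes disagree in direction (cdk8,
    ret, ilk) occupy one row per probe set.
    """
    return _load("zebrafish_hcc_expression_methylation.tsv")


def load_hcc_expression_funnel() -> dict[str, int]:
    """Funnel counts from the expression comparison: genes with altered
    expression, the subset with promoter CGIs, and the subset
    co-represented on the tiling array."""
    df = _load("zebrafish_hcc_expression_funnel.tsv")
    return dict(zip(df["stage"], df["count"].astype(int)))
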