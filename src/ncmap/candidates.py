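"""Published cancer-selective candidate peptides (bundled input table).

The package ships the printed shortlist of noncanonical MHC class I
peptides that survived the 1-TPM healthy-tissue expression cutoff: one row
per (peptide, parent gene) with the reported mean healthy-tissue TPM and
the count of healthy tissues with protein expression (out of 56).  These
values are *inputs* to the selectivity triage, used to exercise the
protein-evidence step on real published numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .selectivity import classify_selectivity_table


def load_candidate_table() -> pd.DataFrame:
    with resources.files("ncmap.data").joinpath(
        "cancer_selective_candidates.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def triage_candidates(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the selectivity triage on the bundled candidate shortlist.

    The shortlist has already survived steps 1 and 2 upstream (no candidate
    was detected in the panel of normals, and each reported mean TPM is
    below the cutoff — asserted here), so the outcome is decided by the
    protein-evidence step: a peptide is cancer selective iff every parent
    gene shows protein expression in zero healthy tissues.

    Returns one row per unique peptide with its selectivity label.
    """
    t = table if table is not None else load_candidate_table()
    if (t["mean_tpm"] >= 1.0).any():
        raise ValueError("candidate table contains a gene at >= 1 TPM")
    expr = (
        t.groupby("gene", as_index=True)[["mean_tpm"]]
        .first()
        .rename(columns={"mean_tpm": "healthy"})
    )
    evidence = dict(
        t.groupby("gene")["tissues_with_protein"].first().astype(int)
    )
    peptide_genes = {
        pep: sorted(sub["gene"]) for pep, sub in t.groupby("peptide")
    }
    labels = classify_selectivity_table(
        peptide_genes, panel=set(), expr=expr, protein_evidence=evidence,
        excluded_tissues=frozenset({"testis"}),
    )
    return pd.DataFrame(
        {"peptide": [x.peptide for x in labels],
         "label": [x.label for x in labels]}
    ).sort_values("peptide", ignore_index=True)
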