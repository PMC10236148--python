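"""Three-step cancer-selectivity triage and HLA binding-matrix analysis.

A peptide is *cancer selective* only if it survives, in order:

1. **Panel of normals** — not detected by MS in any healthy-tissue
   immunopeptidome sample (exact sequence membership).
2. **Transcript expression** — every parent gene's 90th-percentile TPM is
   below the cutoff (default 1 TPM) in every healthy tissue, excluding
   immune-privileged tissues (default: testis).
3. **Protein evidence** — no parent gene shows protein expression in any
   healthy tissue (count of supporting tissues == 0).

Multi-gene peptides must pass steps 2 and 3 for ALL parent genes
(conservative AND).  The first failing step determines the label.

The binding-matrix utilities binarize eluted-ligand percentile ranks at the
strong-binder cutoff (rank <= 0.5%) and compare alleles by cosine distance
of their binary binding profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

DEFAULT_TPM_CUTOFF = 1.0
DEFAULT_EXCLUDED_TISSUES = frozenset({"testis"})
DEFAULT_EL_RANK_THRESHOLD = 0.5  # percent; <= is a strong binder

LABELS = (
    "non_cancer_selective_ms",
    "expressed_above_cutoff",
    "protein_expressed",
    "cancer_selective",
)


@dataclass
class SelectivityLabel:
    peptide: str
    label: str
    evidence: dict = field(default_factory=dict)


def tissue_percentile(
    samples: pd.DataFrame,
    q: float = 90.0,
    method: str = "linear",
) -> pd.DataFrame:
    """Per-(gene, tissue) percentile of sample-level TPM values.

    ``samples`` must have columns ``gene``, ``tissue``, ``tpm``.  Returns a
    gene x tissue matrix; cells without any sample are NaN (missing, not
    zero).  ``method`` is the percentile interpolation ("linear" default,
    "nearest" for nearest-rank).
    """
    for col in ("gene", "tissue", "tpm"):
        if col not in samples.columns:
            raise ValueError(f"samples table lacks required column {col!r}")
    if (samples["tpm"] < 0).any():
        raise ValueError("negative TPM values in samples table")

    def agg(x: pd.Series) -> float:
        return float(np.percentile(x.to_numpy(), q, method=method))

    mat = samples.pivot_table(
        index="gene", columns="tissue", values="tpm", aggfunc=agg
    )
    return mat


def classify_selectivity(
    peptide: str,
    parent_genes: list[str],
    panel: set[str],
    expr: pd.DataFrame,
    protein_evidence: dict[str, int],
    tpm_cutoff: float = DEFAULT_TPM_CUTOFF,
    excluded_tissues: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TISSUES,
    missing: str = "strict",
) -> SelectivityLabel:
    """Apply the three-step triage to one peptide.

    ``expr`` is the gene x tissue matrix of 90th-percentile TPMs.
    ``missing`` controls genes absent from ``expr``/``protein_evidence``:
    "strict" raises, "fail" treats the peptide as not passing that step.
    """
    if not parent_genes:
        raise ValueError(f"peptide {peptide} has no parent genes")
    if peptide in panel:
        return SelectivityLabel(peptide, "non_cancer_selective_ms",
                                {"step": 1})
    tissues = [t for t in expr.columns if t not in excluded_tissues]
    offending: list[tuple[str, str, float]] = []
    for gene in parent_genes:
        if gene not in expr.index:
            if missing == "strict":
                raise KeyError(f"gene {gene!r} absent from expression matrix")
            offending.append((gene, "<missing>", float("nan")))
            continue
        row = expr.loc[gene, tissues]
        above = row[row >= tpm_cutoff].dropna()
        for tissue, val in above.items():
            offending.append((gene, str(tissue), float(val)))
    if offending:
        return SelectivityLabel(
            peptide, "expressed_above_cutoff",
            {"step": 2, "offending": offending},
        )
    expressed: list[tuple[str, int]] = []
    for gene in parent_genes:
        if gene not in protein_evidence:
            if missing == "strict":
                raise KeyError(f"gene {gene!r} absent from protein-evidence table")
            expressed.append((gene, -1))
            continue
        if protein_evidence[gene] > 0:
            expressed.append((gene, protein_evidence[gene]))
    if expressed:
        return SelectivityLabel(
            peptide, "protein_expressed", {"step": 3, "expressed": expressed}
        )
    return SelectivityLabel(peptide, "cancer_selective", {"step": 3})


def classify_selectivity_table(
    peptide_genes: dict[str, list[str]],
    panel: set[str],
    expr: pd.DataFrame,
    protein_evidence: dict[str, int],
    **kwargs,
) -> list[SelectivityLabel]:
    return [
        classify_selectivity(pep, genes, panel, expr, protein_evidence, **kwargs)
        for pep, genes in sorted(peptide_genes.items())
    ]


def build_binding_matrix(
    el_ranks: pd.DataFrame, threshold: float = DEFAULT_EL_RANK_THRESHOLD
) -> pd.DataFrame:
    """Binarize an allele x peptide EL-rank (percent) table: 1 for strong
    binders (rank <= threshold), else 0."""
    if (el_ranks.to_numpy() < 0).any():
        raise ValueError("negative EL rank in input table")
    return (el_ranks <= threshold).astype(np.int8)


def allele_distance(bm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distance between allele binding profiles (rows)."""
    arr = bm.to_numpy(dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        raise ValueError(
            f"allele(s) with all-zero binding vector: "
            f"{', '.join(str(bm.index[i]) for i in zero)}"
        )
    dm = squareform(pdist(arr, metric="cosine"))
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=bm.index, columns=bm.index)


def read_expression_samples(path) -> pd.DataFrame:
    """TSV with columns gene, tissue, sample, tpm."""
    df = pd.read_csv(path, sep="\t")
    return df


def read_protein_evidence(path) -> dict[str, int]:
    """TSV with columns gene, tissues_with_protein (plus optional denominator)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["tissues_with_protein"].astype(int)))
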