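import pytest

from ncmap.fixtures import FixtureSpec, make_reference
from ncmap.genome_model import (
    GeneModel,
    GenomicInterval,
    ReferenceModel,
    TranscriptModel,
)


@pytest.fixture(scope="session")
def fixture42():
    """Seeded synthetic reference with planted ground truth (built once)."""
    return make_reference(FixtureSpec(seed=42))


def make_toy_reference(chrom_seq: str, genes: list[dict]) -> ReferenceModel:
    """Assemble a ReferenceModel from a chromosome string and gene dicts
    with keys: gene_id, strand, exons [(s,e)...], optional cds [(s,e)...],
    optional biotype."""
    models = []
    for g in genes:
        strand = g.get("strand", "+")
        exons = [GenomicInterval("chr1", s, e, strand) for s, e in g["exons"]]
        cds = (
            [GenomicInterval("chr1", s, e, strand) for s, e in g["cds"]]
            if g.get("cds")
            else None
        )
        span = GenomicInterval(
            "chr1",
            g.get("start", min(e.start for e in exons)),
            g.get("end", max(e.end for e in exons)),
            strand,
        )
        models.append(
            GeneModel(
                gene_id=g["gene_id"],
                gene_name=g.get("gene_name", g["gene_id"]),
                biotype=g.get("biotype", "protein_coding"),
                chrom="chr1",
                strand=strand,
                span=span,
                transcripts=[
                    TranscriptModel(
                        transcript_id=g.get("transcript_id", "T_" + g["gene_id"]),
                        exons=exons,
                        cds=cds,
                        strand=strand,
                    )
                ],
            )
        )
    return ReferenceModel(chromosomes={"chr1": chrom_seq}, genes=models)
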