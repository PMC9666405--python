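"""Shared fixtures: packaged gene models and small table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import isojunct as ij
from isojunct.gene_model import GeneModel, load_gene_model, packaged_model_path
from isojunct.junction_quant import JunctionCountTable
from isojunct.longread import LongReadAlignment


@pytest.fixture(scope="session")
def mouse_model() -> GeneModel:
    return load_gene_model(packaged_model_path("tcf4_mouse"))


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    return load_gene_model(packaged_model_path("toy_three_exon"))


MINUS_TOY_YAML = """\
gene: ToyMinus
contig: chrT
strand: "-"
locus: [100, 700]
constitutive_chain: [e2, e3]
splice_features: {}
exons:
  - {name: e3, class: three_prime, start: 100, end: 300}
  - {name: e2, class: internal, start: 400, end: 500}
  - {name: e1, class: five_prime, start: 600, end: 700}
isoforms:
  - name: TOYM-1
    initiating_exon: e1
    diagnostic_junctions: [e1-e2]
    transcript_exons: [e1, e2, e3]
    annotated: true
junctions:
  - {up: e1, down: e2, isoform: TOYM-1}
  - {up: e2, down: e3}
"""


@pytest.fixture(scope="session")
def minus_model(tmp_path_factory) -> GeneModel:
    path = tmp_path_factory.mktemp("models") / "toy_minus.yaml"
    path.write_text(MINUS_TOY_YAML)
    return load_gene_model(path)


def read_from_blocks(blocks, contig="chr18", strand="+", read_id="r1") -> LongReadAlignment:
    """Build a valid alignment from (start, end) genomic block intervals."""
    blocks = sorted(blocks)
    return LongReadAlignment(
        read_id=read_id,
        contig=contig,
        start=blocks[0][0],
        end=blocks[-1][1],
        strand=strand,
        blocks=tuple((s, e - s) for s, e in blocks),
    )


def transcript_read(model, isoform, read_id="r1", **kwargs) -> LongReadAlignment:
    """A full-length read covering the isoform's whole transcript."""
    blocks = model.transcript_blocks(isoform, **kwargs)
    return read_from_blocks(
        blocks, contig=model.contig, strand=model.strand, read_id=read_id
    )


def make_count_table(
    counts: dict[str, list[int]],
    contigs: dict[str, str] | None = None,
    motifs: dict[str, str] | None = None,
    totals: list[float] | None = None,
    meta: pd.DataFrame | None = None,
) -> JunctionCountTable:
    """Small hand-built junction count table for arithmetic tests."""
    n = len(next(iter(counts.values())))
    sample_ids = [f"s{i + 1:02d}" for i in range(n)]
    frame = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"))
    junctions = pd.DataFrame(
        {
            "contig": [(contigs or {}).get(j, "chr18") for j in frame.columns],
            "intron_start": np.arange(len(frame.columns)) * 1000 + 100,
            "intron_end": np.arange(len(frame.columns)) * 1000 + 900,
            "strand": "+",
            "motif": [(motifs or {}).get(j, "canonical") for j in frame.columns],
            "annotated": True,
            "exon_label": "",
            "isoform_label": "",
        },
        index=pd.Index(frame.columns, name="junction_id"),
    )
    if meta is None:
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": "synthetic",
                "tissue": "cortex",
                "age_group": "P3",
                "dataset_id": "sim",
            }
        ).set_index("sample_id")
    tot = pd.Series(
        totals if totals is not None else frame.sum(axis=1).astype(float),
        index=frame.index,
        dtype=float,
    )
    table = JunctionCountTable(counts=frame, junctions=junctions, samples=meta, totals=tot)
    table.validate()
    return table
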