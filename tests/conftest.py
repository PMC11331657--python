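import numpy as np
import pytest

from spliceconcord.events import SpliceEvent
from spliceconcord.io import GenomeSequence


def make_event(
    event_type="SE",
    event_id="1",
    gene_id="g1",
    gene_symbol="G1",
    contig="chr1",
    strand="+",
    coords=None,
    delta_psi=0.3,
    pvalue=0.001,
    fdr=0.01,
    contrast_label="kd1",
    **kw,
):
    """Build a minimal valid SpliceEvent of any type for unit tests."""
    if coords is None:
        if event_type == "SE":
            coords = {"upstream": (50, 80), "target": (100, 200), "downstream": (250, 300)}
        elif event_type == "RI":
            coords = {"upstream": (50, 80), "downstream": (250, 300), "intron": (80, 250)}
        elif event_type == "MXE":
            coords = {
                "upstream": (50, 80), "exon1": (100, 150),
                "exon2": (170, 220), "downstream": (250, 300),
            }
        elif event_type == "A5SS":
            coords = {"long": (100, 300), "short": (100, 250), "flanking": (350, 400)}
        else:  # A3SS
            coords = {"long": (100, 300), "short": (150, 300), "flanking": (50, 80)}
    return SpliceEvent(
        event_id=event_id,
        event_type=event_type,
        gene_id=gene_id,
        gene_symbol=gene_symbol,
        contig=contig,
        strand=strand,
        coords=coords,
        psi_group1=kw.pop("psi_group1", (0.8, 0.7)),
        psi_group2=kw.pop("psi_group2", (0.4, 0.5)),
        delta_psi=delta_psi,
        pvalue=pvalue,
        fdr=fdr,
        ijc_group1=kw.pop("ijc_group1", (10, 12)),
        sjc_group1=kw.pop("sjc_group1", (5, 6)),
        ijc_group2=kw.pop("ijc_group2", (4, 5)),
        sjc_group2=kw.pop("sjc_group2", (9, 8)),
        inc_len=kw.pop("inc_len", 198),
        skip_len=kw.pop("skip_len", 99),
        contrast_label=contrast_label,
        **kw,
    )


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), 2000))
    return GenomeSequence({"chrT": seq})


@pytest.fixture(scope="session")
def small_fixture():
    """One small generated dataset shared by read-only tests."""
    from spliceconcord.simulate import (
        SyntheticConfig,
        generate_event_tables,
        generate_genome_annotation,
    )

    config = SyntheticConfig(
        seed=11, n_events_per_type=20, n_shared_total=50, n_genes=30,
        fdr_significant_fraction=1.0,
    )
    genome, annotation = generate_genome_annotation(config)
    tables, truth = generate_event_tables(config, genome, annotation, ["kd1", "kd2"])
    return config, genome, annotation, tables, truth
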