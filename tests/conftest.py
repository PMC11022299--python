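import pytest

from repurpose import synth


@pytest.fixture
def small_cfg() -> synth.GeneratorConfig:
    """A small but fully structured synthetic universe (fast everywhere)."""
    return synth.make_config(
        seed=7,
        n_genes=12,
        n_compounds=30,
        n_patients=20,
        n_cell_lines=40,
        n_tumor_samples=500,
        planted_pairs=[
            ("DRUG001", "GENE001"),
            ("DRUG002", "GENE001"),
            ("DRUG003", "GENE002"),
            ("DRUG004", "GENE002"),
        ],
        planted_offlabel_pairs=[("DRUG010", "GENE003"), ("DRUG011", "GENE004")],
    )


@pytest.fixture
def probe_tsv(tmp_path):
    """Write a tiny probe table file and return its path."""

    def _write(rows, header="compound_id\ttarget_gene\tglobal_score"):
        path = tmp_path / "probes.tsv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
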