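"""Shared fixtures: hand-written ontologies and a generated knowledge graph."""

import pathlib

import pytest

from phenoprio.synthetic_kg import GeneratorConfig, generate_kg

MINI_OBO = """\
format-version: 1.4
ontology: hp-test

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: child
is_a: HP:0000001 ! root

[Term]
id: HP:0000003
name: grandchild
is_a: HP:0000002 ! child

[Term]
id: HP:0000009
name: old term
is_obsolete: true
replaced_by: HP:0000002
"""

TABULAR_FIXTURE = {
    "concepts.tsv": """\
cui\tname\tsemantic_type
C0000001\talpha disease\tdisease
C0000002\tbeta finding\tfinding
""",
    "gda.tsv": """\
gene\tcui\tscore\tpmids
10\tC0000001\t0.9\t111,222
10\tC0000002\t0.3\t
20\tC0000001\t0.5\t333
""",
    "hpo2cui_metathesaurus.tsv": """\
hpo\tcui
HP:0000002\tC0000001
""",
    "hpo2ordo2cui_hoom.tsv": """\
hpo\tordo\tcui
HP:0000002\tOrphanet:123\tC0000002
""",
    "hpo2cui_pda.tsv": """\
hpo\tcui
HP:0000003\tC0000002
""",
}


@pytest.fixture
def mini_obo(tmp_path) -> pathlib.Path:
    p = tmp_path / "mini.obo"
    p.write_text(MINI_OBO, encoding="utf-8")
    return p


@pytest.fixture
def tabular_store_dir(tmp_path) -> pathlib.Path:
    d = tmp_path / "store"
    d.mkdir()
    for name, text in TABULAR_FIXTURE.items():
        (d / name).write_text(text, encoding="utf-8")
    return d


@pytest.fixture(scope="session")
def kg(tmp_path_factory):
    """A mid-size generated knowledge graph written to disk once per session."""
    outdir = tmp_path_factory.mktemp("kg")
    return generate_kg(GeneratorConfig(seed=42, n_orphan_concepts=16), outdir)
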