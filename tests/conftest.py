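import pytest

from ddsn.ontology import compute_ic
from ddsn.synthdata import fig1_dataset

FIG1_OBO = """format-version: 1.2
ontology: fig1

[Term]
id: 0
name: root

[Term]
id: 1
name: term one
is_a: 0

[Term]
id: 4
name: term four
is_a: 0

[Term]
id: 2
name: term two
is_a: 4

[Term]
id: 3
name: term three
is_a: 4

[Term]
id: 9
name: retired term
is_obsolete: true

[Term]
id: 7
name: inheritance branch

[Term]
id: 8
name: autosomal something
is_a: 7
"""


@pytest.fixture(scope="session")
def fig1():
    """The worked example: DAG, annotations, series, class labels, IC."""
    dag, annotations, series, classes = fig1_dataset()
    ic = compute_ic(dag, annotations)
    return {
        "dag": dag,
        "annotations": annotations,
        "series": series,
        "classes": classes,
        "ic": ic,
    }


@pytest.fixture(scope="session")
def fig1_obo_text():
    """OBO serialization of the worked example plus an out-of-subtree
    branch (terms 7, 8) and an obsolete term (9)."""
    return FIG1_OBO
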