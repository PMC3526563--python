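import numpy as np
import pytest

from goqa.neighbors import Slist, SlistRecord
from goqa.ontology import GODag, GOTerm, parse_obo

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: mid
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: molecular_function
is_a: GO:0000002
"""

SIBLINGS_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: sib_a
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: sib_b
namespace: molecular_function
is_a: GO:0000001
"""


@pytest.fixture
def chain_dag():
    """R <- B <- A via is_a: GO:0000003 is the leaf."""
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def siblings_dag():
    """Two siblings GO:0000002, GO:0000003 under one root."""
    return parse_obo(SIBLINGS_OBO)


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> R with mixed relations."""
    terms = {
        "GO:0000001": GOTerm("GO:0000001", "root", "molecular_function"),
        "GO:0000002": GOTerm("GO:0000002", "b", "molecular_function",
                             parents=(("GO:0000001", "is_a"),)),
        "GO:0000003": GOTerm("GO:0000003", "c", "molecular_function",
                             parents=(("GO:0000001", "part_of"),)),
        "GO:0000004": GOTerm("GO:0000004", "a", "molecular_function",
                             parents=(("GO:0000002", "is_a"), ("GO:0000003", "is_a"))),
    }
    return GODag(terms)


def make_slist(fs_values, z_scores, model_id="model"):
    """Slist whose ranking reproduces the given top-to-bottom order."""
    records = tuple(
        SlistRecord(f"n{i:03d}-A", float(z), float(fs))
        for i, (fs, z) in enumerate(zip(fs_values, z_scores))
    )
    return Slist(model_id=model_id, records=records, n_input_neighbors=len(records))


def labelled_slist(labels, zs=None, model_id="model"):
    """Slist with FS 0.9 for positives / 0.1 for negatives at threshold 0.5,
    ranked in the given order via decreasing Z."""
    n = len(labels)
    if zs is None:
        zs = [float(n - i) for i in range(n)]
    fs = [0.9 if lab else 0.1 for lab in labels]
    return make_slist(fs, zs, model_id)


def random_slist(rng: np.random.Generator, max_records: int = 50) -> Slist:
    n = int(rng.integers(1, max_records + 1))
    fs = rng.random(n)
    z = rng.random(n) * 30.0
    if n > 1 and rng.random() < 0.3:  # exercise the Z tie-break
        z = np.round(z, 1)
    return make_slist(fs, z)
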