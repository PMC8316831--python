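import numpy as np
import pytest

from synnet.fixtures import demo_treebank, reference_panel
from synnet.network import SyntacticNetwork, build_network

# rows of the bundled two-sentence worked example in the tabular dialect
DEMO_TABLE_ROWS = [
    "s1\t1\tTa\tr\t2\tKan\tSBV",
    "s1\t2\tKan\tv\t0\t/\tHED",
    "s1\t3\tShu\tn\t2\tKan\tVOB",
    "s2\t1\tTa\tr\t4\tKan\tSBV",
    "s2\t2\tZai\tp\t4\tKan\tADV",
    "s2\t3\tXuexiao\tn\t2\tZai\tPOB",
    "s2\t4\tKan\tv\t0\t/\tHED",
    "s2\t5\tShu\tn\t4\tKan\tVOB",
]

DEMO_CONLLU = """\
# sent_id = s1
1\tTa\t_\tr\t_\t_\t2\tSBV\t_\t_
2\tKan\t_\tv\t_\t_\t0\tHED\t_\t_
3\tShu\t_\tn\t_\t_\t2\tVOB\t_\t_

# sent_id = s2
1\tTa\t_\tr\t_\t_\t4\tSBV\t_\t_
2\tZai\t_\tp\t_\t_\t4\tADV\t_\t_
3\tXuexiao\t_\tn\t_\t_\t2\tPOB\t_\t_
4\tKan\t_\tv\t_\t_\t0\tHED\t_\t_
5\tShu\t_\tn\t_\t_\t4\tVOB\t_\t_
"""


@pytest.fixture
def demo_table_file(tmp_path):
    path = tmp_path / "demo.tsv"
    path.write_text("\n".join(DEMO_TABLE_ROWS) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def demo_conllu_file(tmp_path):
    path = tmp_path / "demo.conllu"
    path.write_text(DEMO_CONLLU, encoding="utf-8")
    return path


@pytest.fixture
def toy_treebank():
    return demo_treebank()


@pytest.fixture
def toy_network(toy_treebank):
    return build_network(toy_treebank)


@pytest.fixture
def panel():
    return reference_panel()


def random_network(rng: np.random.Generator, max_n: int = 30) -> SyntacticNetwork:
    """A random small simple graph for oracle cross-checks."""
    n = int(rng.integers(2, max_n + 1))
    max_m = n * (n - 1) // 2
    m = int(rng.integers(1, max_m + 1))
    net = SyntacticNetwork()
    for i in range(n):
        net.add_vertex(f"v{i}")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    idx = rng.choice(len(pairs), size=m, replace=False)
    for k in idx:
        i, j = pairs[k]
        net.add_edge(f"v{i}", f"v{j}")
    return net
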