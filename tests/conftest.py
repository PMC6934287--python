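import warnings

import numpy as np
import pandas as pd
import pytest

import convsearch as cs

# simulator eligibility warnings are noise in tests
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def three_tip():
    return cs.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced16():
    """Balanced ultrametric 16-tip tree, all root-to-tip paths length 4."""
    def sub(labels, depth):
        if len(labels) == 1:
            return f"{labels[0]}:1"
        half = len(labels) // 2
        return f"({sub(labels[:half], depth + 1)},{sub(labels[half:], depth + 1)}):1"
    labels = [f"t{i}" for i in range(16)]
    half = len(labels) // 2
    nwk = f"({sub(labels[:half], 1)},{sub(labels[half:], 1)});"
    return cs.from_newick_string(nwk)


@pytest.fixture
def bd_tree():
    rng = np.random.default_rng(42)
    return cs.simulate_bd_tree(0.5, 0.2, 40, rng)


@pytest.fixture
def bd_tree_phen(bd_tree):
    rng = np.random.default_rng(43)
    return bd_tree, cs.simulate_bm(bd_tree, 3, 1.0, rng)


def random_phenotype(tree, p=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(tree.ntips, p)),
                        index=tree.tip_labels,
                        columns=[f"v{i+1}" for i in range(p)])
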