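import numpy as np
import pandas as pd
import pytest
from io import StringIO

from skbio import TreeNode

from hrsip.io import CountMatrix, SampleMeta


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(10, 4)),
        index=[f"OTU.{i}" for i in range(1, 11)],
        columns=[f"s{j}" for j in range(1, 5)],
    )
    return CountMatrix(data)


@pytest.fixture
def gradient_meta() -> SampleMeta:
    rows = []
    for gid, treatment in (("ctl_d1", "control"), ("xyl_d1", "13C-xylose")):
        for i, rho in enumerate(np.linspace(1.68, 1.76, 10)):
            rows.append(
                {
                    "sample_id": f"{gid}_f{i}",
                    "treatment": treatment,
                    "day": 1,
                    "gradient_id": gid,
                    "density": rho,
                    "is_fractionated": True,
                }
            )
    return SampleMeta(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def balanced_tree() -> TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1) — the 4-tip workhorse for phylo oracles."""
    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
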