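import numpy as np
import pandas as pd
import pytest

from maplkit import CountMatrix, make_reference_db


def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance (independent oracle for the clustering
    and mismatch logic; deliberately not edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def connected_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Union-find components oracle."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def toy_count_matrix(
    counts: dict[str, list[int]],
    otus: list[str],
    roles: dict[str, str] | None = None,
) -> CountMatrix:
    """Build a CountMatrix from a {column: counts} dict.

    Column ids must follow "<bio>|R<k>"; columns named "NC*" default to
    negative controls.
    """
    meta_rows = []
    for col in counts:
        bio, _, rep = col.rpartition("|R")
        role = (roles or {}).get(col, "negative_control" if col.startswith("NC") else "specimen")
        meta_rows.append(
            {
                "sample_replicate_id": col,
                "biological_id": bio,
                "replicate_index": int(rep),
                "role": role,
                "stage": "NA",
                "site": "NA",
                "field": "NA",
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample_replicate_id")
    return CountMatrix(pd.DataFrame(counts, index=otus), meta)


@pytest.fixture(scope="session")
def small_db():
    return make_reference_db(n_parasitoids=3, divergence=0.05, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
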