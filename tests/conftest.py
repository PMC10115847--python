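import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from epivep.structure import structural_contacts
from epivep.synthetic import (
    SyntheticSpec,
    synth_labels_on_contacts,
    synth_structure,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def structure(spec):
    return synth_structure(spec)


@pytest.fixture(scope="session")
def contact_graph(structure):
    return structural_contacts(structure)


@pytest.fixture(scope="session")
def planted(structure, spec):
    """(CuratedTrainingSet, position-label map) with spatially clustered labels."""
    return synth_labels_on_contacts(structure, spec)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def brute_force_contacts(positions, coords, cutoff, min_separation=0):
    """All-pairs distance scan; the oracle for structural_contacts."""
    pairs = set()
    n = len(positions)
    for a in range(n):
        for b in range(a + 1, n):
            d = float(np.sqrt(np.sum((coords[a] - coords[b]) ** 2)))
            i, j = int(positions[a]), int(positions[b])
            if d < cutoff and abs(i - j) > min_separation:
                pairs.add((min(i, j), max(i, j)))
    return pairs


def pair_counting_auc(truth, scores):
    """Exhaustive positive/negative pair counting; ties count half."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mcc_formula(tp, fp, tn, fn):
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def best_stump_oracle(X, r):
    """Exhaustive best single split by SSE over all (feature, midpoint)."""
    def sse(v):
        return float(np.sum(v**2) - np.sum(v) ** 2 / len(v)) if len(v) else 0.0

    base = sse(r)
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            left, right = r[X[:, f] < thr], r[X[:, f] >= thr]
            gain = base - sse(left) - sse(right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, f, thr)
    return best


@pytest.fixture(scope="session")
def oracles():
    class Oracles:
        contacts = staticmethod(brute_force_contacts)
        auc = staticmethod(pair_counting_auc)
        mcc = staticmethod(mcc_formula)
        stump = staticmethod(best_stump_oracle)

    return Oracles
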