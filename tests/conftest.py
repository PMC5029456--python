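import numpy as np
import pytest

import estrodyn as ed


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset shared across tests."""
    return ed.generate_dataset(ed.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_de(default_dataset):
    return ed.run_de(default_dataset.mrna_counts, default_dataset.metadata)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for pipeline-level tests."""
    cfg = ed.SimulationConfig(n_genes=120, n_mirnas=6, n_targets=9, seed=7)
    return cfg, ed.generate_dataset(cfg)


def brute_force_seed_scan(utr: str, seed_rna: str):
    """Independent oracle for canonical seed-site scanning.

    Walks every position of the UTR and classifies by explicit string
    comparison against the three site-class definitions, checking the
    8mer-suppression context characters directly.
    """
    s = utr.upper().replace("U", "T")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seed = seed_rna.upper().replace("U", "T")
    rc7 = "".join(comp[c] for c in reversed(seed))        # nt 2-8
    rc6 = "".join(comp[c] for c in reversed(seed[:6]))    # nt 2-7
    hits = []
    n = len(s)
    for i in range(n):
        if s[i:i + 8] == rc7 + "A":
            hits.append((i, "8mer"))
        if s[i:i + 7] == rc7 and s[i + 7:i + 8] != "A":
            hits.append((i, "7mer-m8"))
        if s[i:i + 7] == rc6 + "A":
            # suppress when part of an 8mer starting one position left
            if not (i >= 1 and s[i - 1:i + 7] == rc7 + "A"):
                hits.append((i, "7mer-1A"))
    return sorted(hits)


def dense_char_direction(X_a, X_b, gamma=0.5):
    """Brute-force gene-space characteristic direction (small matrices).

    Solves (gamma*S + (1-gamma)*(tr(S)/d)*I) b = mu_b - mu_a with the full
    genes x genes within-class covariance S; d is the rank of the globally
    centered data, matching the shrinkage target definition.
    """
    X_a = np.asarray(X_a, float)
    X_b = np.asarray(X_b, float)
    mu_a, mu_b = X_a.mean(0), X_b.mean(0)
    delta = mu_b - mu_a
    X = np.vstack([X_a, X_b])
    Xc = X - X.mean(0)
    d = np.linalg.matrix_rank(Xc)
    W = np.vstack([X_a - mu_a, X_b - mu_b])
    S = W.T @ W / max(len(X) - 2, 1)
    M = gamma * S + (1 - gamma) * (np.trace(S) / d) * np.eye(S.shape[0])
    b = np.linalg.solve(M, delta)
    b = b / np.linalg.norm(b)
    if b @ delta < 0:
        b = -b
    return b
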