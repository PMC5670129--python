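import numpy as np
import pytest

import hierclass as hc


@pytest.fixture(scope="session")
def separated_hierarchy():
    """Small well-separated two-level hierarchy: (X, lineages, tree)."""
    spec = hc.TreeSpec(
        branching=[2, 2], samples_per_leaf=16, n_features=20,
        separation=6.0, seed=11,
    )
    return hc.gen_hierarchical_gaussians(spec)


@pytest.fixture(scope="session")
def two_gaussians():
    """Two well-separated classes (delta-mu = 6 sigma, 40/class, d=10)."""
    rng = np.random.default_rng(42)
    d = 10
    mu = np.zeros(d)
    mu[0] = 6.0
    X = np.vstack(
        [rng.standard_normal((40, d)) + mu, rng.standard_normal((40, d))]
    )
    y = ["pos"] * 40 + ["neg"] * 40
    return X, y


@pytest.fixture(scope="session")
def bacterial_style_lineages():
    """Fifteen six-rank lineages with the structural quirks of a real bacterial
    taxonomy: multi-species genera, single-species genera, and a repeated
    species epithet under two genera."""
    return [
        "G+;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;agalactiae",
        "G+;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;pyogenes",
        "G+;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;pneumoniae",
        "G+;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus;aureus",
        "G+;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus;epidermidis",
        "G+;Clostridia;Clostridiales;Clostridiaceae;Clostridium;difficile",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Escherichia;coli",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Klebsiella;pneumoniae",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Klebsiella;oxytoca",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Enterobacter;cloacae",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Enterobacter;aerogenes",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Serratia;marcescens",
        "G-;Gammaproteo;Enterobacterales;Enterobacteriaceae;Proteus;mirabilis",
        "G-;Gammaproteo;Pseudomonadales;Pseudomonadaceae;Pseudomonas;aeruginosa",
        "G-;Gammaproteo;Enterobacterales;Morganellaceae;Morganella;pneumoniae",
    ]
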