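import numpy as np
import pytest
from scipy.linalg import expm

import tpsevo as t


@pytest.fixture(scope="session")
def jtt():
    return t.SubstitutionModel.jtt(alpha=1.0, K=4)


@pytest.fixture(scope="session")
def poisson1():
    """Single-rate equal-exchangeability model."""
    return t.SubstitutionModel.poisson(K=1)


def four_tip_instance(tips: dict, lengths=(0.13, 0.25, 0.07, 0.31, 0.12, 0.19)):
    """((A,B)n1,(C,D)n2)root with the given six branch lengths."""
    a, b, x, c, d, y = lengths
    fa = "".join(f">{k}\n{v}\n" for k, v in tips.items())
    nwk = f"((A:{a},B:{b})n1:{x},(C:{c},D:{d})n2:{y})root;"
    return t.PhyloInstance.from_strings(nwk, fa)


def enumerate_likelihood_posterior(instance, model, lengths, node):
    """Exhaustive-enumeration oracle for the ((A,B)n1,(C,D)n2)root shape.

    Sums the joint likelihood over all 20^3 internal-state assignments per
    site, using scipy's matrix exponential for transition probabilities
    (independent of the pruning implementation).  Returns (per-site logL,
    posterior matrix at `node`).
    """
    a, b, x, c, d, y = lengths
    aln = instance.alignment
    Q = model.rate_matrix
    L = instance.L
    site_lik = np.zeros(L)
    post = np.zeros((L, 20))
    node_axis = {"root": 0, "n1": 1, "n2": 2}[node]
    for rate in model.category_rates:
        P = {bl: expm(Q * rate * bl) for bl in set(lengths)}
        # joint[root, n1, n2] per site
        for s in range(L):
            ia = [t.ALPHABET.index(aln[k][s]) for k in "ABCD"]
            joint = (
                model.pi[:, None, None]
                * P[x][:, :, None] * P[y][:, None, :]
                * (P[a][:, ia[0]] * P[b][:, ia[1]])[None, :, None]
                * (P[c][:, ia[2]] * P[d][:, ia[3]])[None, None, :]
            )
            site_lik[s] += joint.sum() / model.K
            axes = tuple(i for i in range(3) if i != node_axis)
            post[s] += joint.sum(axis=axes)
    return np.log(site_lik), post / post.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def enumeration_oracle():
    return enumerate_likelihood_posterior


@pytest.fixture(scope="session")
def study():
    """Default synthetic study bundle (seed 7)."""
    return t.make_study(seed=7)


def profile_from(comp: dict, enzyme: str = "e", n: int = 3) -> t.ProductProfile:
    vocab = tuple(comp)
    mean = np.array([comp[p] for p in vocab], float)
    return t.ProductProfile(enzyme, vocab, mean / mean.sum(),
                            np.zeros(len(vocab)), n=n, active=True)


@pytest.fixture(scope="session")
def make_profile():
    return profile_from
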