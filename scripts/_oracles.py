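"""Independent brute-force oracles used by the acceptance script."""

import numpy as np


def brute_force_ce(u, v):
    k_dim, n = u.shape
    acc = 0.0
    for i in range(n):
        for k in range(k_dim):
            acc += v[k, i] * np.log(max(u[k, i], 1e-7))
    return -acc / n


def brute_force_dice(u, v, eps=1e-5):
    k_dim, n = u.shape
    acc = 0.0
    for k in range(k_dim):
        num = sum(u[k, i] * v[k, i] for i in range(n)) + eps
        den = sum(u[k, i] for i in range(n)) + sum(v[k, i] for i in range(n)) + eps
        acc += num / den
    return -2.0 / k_dim * acc


def random_instance(rng, max_side=4, max_k=3):
    k = int(rng.integers(2, max_k + 1))
    n = int(rng.integers(1, max_side**3 + 1))
    logits = rng.normal(size=(k, n))
    u = np.exp(logits) / np.exp(logits).sum(axis=0)
    labels = rng.integers(0, k, size=n)
    v = np.zeros((k, n))
    v[labels, np.arange(n)] = 1
    return u, v
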