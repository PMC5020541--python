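"""Synthetic expression data with known topic structure along a trajectory.

The generator follows the LDA generative process exactly: per-topic gene
distributions phi with disjoint high-mass "anchor" gene blocks (the planted
gene sets), per-cell topic mixtures theta that move along a piecewise-linear
path through the corners of the topic simplex as pseudotime advances, and
multinomial token sampling.  Branching populations diverge at pseudotime
0.5.  Per-cell Dirichlet jitter grows with pseudotime, so later stages are
more dispersed — the biological assumption behind automatic start-group
detection holds by construction.

Everything is deterministic given the seed (PCG64 streams spawned from one
SeedSequence), so fixtures are generated at test time rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated count matrix."""

    theta_true: np.ndarray       # (M, K)
    phi_true: np.ndarray         # (K, V)
    pseudotime_true: np.ndarray  # (M,) in [0, 1]
    branch_true: list[str]
    group_labels: list[str]      # stage label per cell (pseudotime quartile)
    planted_terms: dict[int, set[str]]  # topic (1-based) -> anchor gene ids
    cell_ids: list[str]
    gene_ids: list[str]
    seed: int
    topic_counts: np.ndarray | None = None  # (M, K) tokens drawn per topic

    def groups(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.group_labels))

    def group_order(self) -> list[str]:
        seen: list[str] = []
        for lab in sorted(set(self.group_labels)):
            seen.append(lab)
        return seen

    def truth_ranks(self) -> dict[str, float]:
        return {c: float(t) for c, t in zip(self.cell_ids, self.pseudotime_true)}


def _anchor_phi(K: int, V: int, rng: np.random.Generator,
                anchor_mass: float = 0.7) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Dirichlet(0.1) topic-gene rows with disjoint boosted anchor blocks."""
    block = max(1, V // (2 * K))
    phi = rng.dirichlet(np.full(V, 0.1), size=K)
    anchors: dict[int, list[int]] = {}
    for k in range(K):
        idx = list(range(k * block, (k + 1) * block))
        anchors[k + 1] = idx
        w = rng.dirichlet(np.full(block, 1.0))
        row = phi[k] * (1.0 - anchor_mass)
        row[idx] = 0.0
        row = row / row.sum() * (1.0 - anchor_mass)
        row[idx] = anchor_mass * w
        phi[k] = row / row.sum()
    return phi, anchors


def _path_theta(t: float, K: int) -> np.ndarray:
    """Point at pseudotime t on the piecewise-linear path e_1 -> ... -> e_K."""
    if K == 1:
        return np.ones(1)
    seg = t * (K - 1)
    i = min(int(seg), K - 2)
    frac = seg - i
    v = np.zeros(K)
    v[i] = 1.0 - frac
    v[i + 1] = frac
    return v


def _branch_theta(t: float, K: int, branch: int, branches: int) -> np.ndarray:
    """Branching path: common trunk until t=0.5, then branch-specific corner."""
    if branches == 1:
        return _path_theta(t, K)
    if t <= 0.5:
        # trunk travels e_1 -> e_2 ... over the first ceil(K/branches) corners
        return _path_theta(t, K)
    v_trunk = _path_theta(0.5, K)
    target = np.zeros(K)
    target[K - 1 - branch] = 1.0  # each branch heads to a distinct corner
    frac = (t - 0.5) / 0.5
    return (1 - frac) * v_trunk + frac * target


def generate_trajectory(M: int = 80, V: int = 500, K: int = 4,
                        branches: int = 1, tokens_per_cell: int = 1000,
                        noise: float = 0.1, seed: int = 0,
                        anchor_mass: float = 0.7
                        ) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate an LDA-structured population along a known trajectory.

    Parameters
    ----------
    M, V, K : cells, genes, topics.
    branches : 1 for a linear continuum; >1 for lineages diverging at
        pseudotime 0.5 (requires K >= branches).
    tokens_per_cell : exact total count per cell (>= 100).
    noise : Dirichlet jitter scale on theta; 0 puts theta exactly on the
        piecewise-linear simplex path.  Jitter grows linearly with
        pseudotime so late stages are more dispersed.
    """
    if not (K >= branches >= 1):
        raise ValueError("need K >= branches >= 1")
    if tokens_per_cell < 100:
        raise ValueError("tokens_per_cell must be >= 100")
    if M < 4:
        raise ValueError("need at least 4 cells")
    if not (0 <= noise <= 1):
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2718]))

    phi, anchor_idx = _anchor_phi(K, V, rng, anchor_mass)
    gene_ids = [f"g{j:05d}" for j in range(V)]
    cell_ids = [f"c{i:04d}" for i in range(M)]
    planted = {k: {gene_ids[j] for j in idx} for k, idx in anchor_idx.items()}

    # equal branch sizes; pseudotime uniform grid within each branch
    branch_of = [i % branches for i in range(M)]
    per_branch: dict[int, list[int]] = {b: [] for b in range(branches)}
    for i, b in enumerate(branch_of):
        per_branch[b].append(i)
    pseudotime = np.zeros(M)
    for b, members in per_branch.items():
        nb = len(members)
        for r, i in enumerate(members):
            pseudotime[i] = r / max(nb - 1, 1)

    theta = np.zeros((M, K))
    for i in range(M):
        t = pseudotime[i]
        base = _branch_theta(t, K, branch_of[i], branches)
        if noise > 0:
            # jitter toward a random simplex point with a deterministic L1
            # magnitude w that grows linearly with pseudotime, so intra-stage
            # dispersion increases along the trajectory by construction
            w = min(1.0, noise * (0.25 + 1.5 * t))
            u = rng.dirichlet(np.ones(K))
            for _ in range(64):  # reject draws too close to the path point
                if np.abs(u - base).sum() >= 0.5:
                    break
                u = rng.dirichlet(np.ones(K))
            s = min(1.0, w / np.abs(u - base).sum())
            theta[i] = (1.0 - s) * base + s * u
        else:
            theta[i] = base

    counts = np.zeros((V, M), dtype=np.int64)
    topic_tokens = np.zeros((M, K), dtype=np.int64)
    for i in range(M):
        topic_tokens[i] = rng.multinomial(tokens_per_cell, theta[i])
        col = np.zeros(V, dtype=np.int64)
        for k in range(K):
            if topic_tokens[i, k]:
                col += rng.multinomial(topic_tokens[i, k], phi[k])
        counts[:, i] = col

    stage = np.minimum((pseudotime * 4).astype(int), 3)
    labels = [f"t{s}" for s in stage]
    truth = SyntheticTruth(theta_true=theta, phi_true=phi,
                           pseudotime_true=pseudotime,
                           branch_true=[f"b{b}" for b in branch_of],
                           group_labels=labels, planted_terms=planted,
                           cell_ids=cell_ids, gene_ids=gene_ids, seed=seed,
                           topic_counts=topic_tokens)
    cm = CountMatrix(counts, gene_ids, cell_ids,
                     groups=truth.groups(), group_order=truth.group_order(),
                     provenance={"generator": "trajectory", "seed": seed,
                                 "K": K, "branches": branches,
                                 "tokens_per_cell": tokens_per_cell,
                                 "noise": noise})
    _assert_generator_contract(cm, truth, tokens_per_cell, noise)
    return cm, truth


def _assert_generator_contract(cm: CountMatrix, truth: SyntheticTruth,
                               tokens_per_cell: int, noise: float) -> None:
    """The generator's documented structure is checked on every fixture."""
    assert np.all(cm.counts.sum(axis=0) == tokens_per_cell)
    assert np.allclose(truth.theta_true.sum(axis=1), 1.0)
    assert np.allclose(truth.phi_true.sum(axis=1), 1.0)
    sets = list(truth.planted_terms.values())
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert not (sets[i] & sets[j]), "anchor blocks must be disjoint"
    if noise > 0 and len(set(truth.group_labels)) >= 2:
        # jitter around the noiseless path grows from first to last stage
        K = truth.phi_true.shape[0]
        branches = len(set(truth.branch_true))
        resid = np.empty(len(truth.cell_ids))
        for i, t in enumerate(truth.pseudotime_true):
            b = int(truth.branch_true[i][1:])
            base = _branch_theta(float(t), K, b, branches)
            resid[i] = np.abs(truth.theta_true[i] - base).sum()
        labs = sorted(set(truth.group_labels))
        disp = [float(np.mean(resid[[i for i, l in enumerate(truth.group_labels)
                                     if l == lab]])) for lab in labs]
        assert disp[0] < disp[-1], \
            "theta jitter must increase along the trajectory"


def generate_null(M: int = 40, V: int = 300, tokens_per_cell: int = 1000,
                  seed: int = 0) -> CountMatrix:
    """Exchangeable cells drawn from one shared gene distribution.

    No latent structure: useful for type-I-error calibration and for
    degenerate-tree behaviour.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3141]))
    phi = rng.dirichlet(np.full(V, 0.5))
    gene_ids = [f"g{j:05d}" for j in range(V)]
    cell_ids = [f"c{i:04d}" for i in range(M)]
    counts = np.zeros((V, M), dtype=np.int64)
    for i in range(M):
        counts[:, i] = rng.multinomial(tokens_per_cell, phi)
    return CountMatrix(counts, gene_ids, cell_ids,
                       provenance={"generator": "null", "seed": seed,
                                   "tokens_per_cell": tokens_per_cell})
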