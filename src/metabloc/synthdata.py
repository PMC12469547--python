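"""Synthetic two-group, block-structured urine metabolomics datasets.

The generator emulates the statistical features of a preterm (Prem) vs
full-term (Term) neonatal urine study: unbalanced group sizes, log-normal
metabolite abundances, multiplicative per-sample dilution (what PQN is
designed to remove), a planted fraction of group-differential metabolites
with signed log2 fold changes, block-structured correlation among
metabolites sharing a functional annotation, and group-specific rewiring
of block-block dependence.  Every downstream stage can therefore be
tested against a known ground truth without any external data.

Structure of the latent layer
-----------------------------
Each functional block carries two per-sample latent factors:

* ``z_k`` — block *activity*, shared by all members, independent of the
  group label; this is the within-block correlation that the per-block
  OPLS-DA files away as orthogonal variation;
* ``v_k`` — block *expression intensity*: each sample expresses the
  block's dysregulation signature with its own intensity, so the
  realized effect of a differential metabolite varies around the
  planted group shift.  The intensities are correlated along a
  spanning tree of blocks — the system's inter-function "wiring" —
  and the Prem group's tree is the Term tree with a configurable
  number of edges *rewired*.  The rewired (new) edges are the planted
  Prem-specific block dependencies; the shared edges cancel when the
  Term network is subtracted from the Prem one.  A tree keeps every
  planted edge identifiable as a direct partial correlation and gives
  the differential network genuine betweenness hubs.

Because ``v`` modulates effects *along the fold-change pattern* (the
class-predictive direction), the per-block OPLS-DA t1 retains it, which
is exactly the premise of correlating block scores within a group.
Differential metabolites concentrate in a minority of "hot" blocks,
but every block keeps a few anchor markers (its strongest effects), so
each block score stays informative about the block's intensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import BlockAnnotation, FeatureMatrix

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "generate_dataset",
    "write_fixtures",
    "read_truth",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the generative model.

    Defaults emulate the NMR-like arm of a preterm/term urine study:
    96 Term vs 45 Prem samples, 74 features organized in 14 functional
    blocks, ~46% of metabolites group-differential with |log2FC| in
    [0.2, 1.5] split evenly up/down.

    Parameters
    ----------
    dilution_sd
        SD (log scale) of the per-sample log-normal dilution factor.
    within_block_rho
        Target pairwise |correlation| (log scale) between metabolites of
        a shared block, realized via the per-block latent factor.
    n_prem_specific_edges
        Number of wiring-tree edges rewired in the Prem group; the new
        edges are the planted Prem-specific block dependencies.
    block_edge_rho
        Intensity-factor correlation along each wiring edge.
    severity_sd
        SD of the per-sample expression-intensity modulation: a
        differential member's realized effect fluctuates around the
        planted shift by ``severity_sd * fc * v`` (standard-normal v).
    frac_hot_blocks, hot_block_boost
        Fraction of blocks designated "hot" and the sampling-weight
        multiplier concentrating differential metabolites into them.
    min_anchor_per_block
        Minimum number of differential primary members ("anchor
        markers") allotted to every block before the hot-block
        concentration applies.
    noise_cv
        Coefficient of variation of the multiplicative log-normal
        measurement noise.
    """

    n_term: int = 96
    n_prem: int = 45
    n_metabolites: int = 74
    n_blocks: int = 14
    max_blocks_per_metabolite: int = 3
    frac_differential: float = 0.46
    log2fc_magnitudes: tuple[float, float] = (0.2, 1.5)
    dilution_sd: float = 0.4
    within_block_rho: float = 0.2
    n_prem_specific_edges: int = 13
    block_edge_rho: float = 0.7
    severity_sd: float = 0.7
    frac_hot_blocks: float = 0.25
    hot_block_boost: float = 4.0
    min_anchor_per_block: int = 2
    noise_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_term", "n_prem", "n_metabolites", "n_blocks"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_term + self.n_prem < 10:
            raise ValueError("n_term + n_prem must be at least 10")
        if not 1 <= self.max_blocks_per_metabolite <= 3:
            raise ValueError("max_blocks_per_metabolite must be in {1, 2, 3}")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must lie in [0, 1]")
        lo, hi = self.log2fc_magnitudes
        if lo < 0 or hi < lo:
            raise ValueError("log2fc_magnitudes must be an ordered pair of non-negative reals")
        if self.dilution_sd < 0:
            raise ValueError("dilution_sd must be non-negative")
        for name in ("within_block_rho", "block_edge_rho"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_prem_specific_edges < 0:
            raise ValueError("n_prem_specific_edges must be non-negative")
        if self.n_prem_specific_edges > self.n_blocks - 1:
            raise ValueError(
                "n_prem_specific_edges must not exceed n_blocks - 1 "
                "(planted edges form a tree)"
            )
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be non-negative")
        if not 0.0 <= self.frac_hot_blocks <= 1.0:
            raise ValueError("frac_hot_blocks must lie in [0, 1]")
        if self.hot_block_boost < 1.0:
            raise ValueError("hot_block_boost must be at least 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    differential_flags: pd.Series
    planted_log2fc: pd.Series
    block_membership: dict[str, tuple[str, ...]]
    prem_specific_block_edges: set[tuple[str, str]]
    dilution_factors: pd.Series

    def __post_init__(self) -> None:
        zero_where_flat = (self.planted_log2fc[~self.differential_flags] == 0).all()
        if not zero_where_flat:
            raise ValueError("planted_log2fc must be 0 wherever differential_flags is False")
        for a, b in self.prem_specific_block_edges:
            if a == b:
                raise ValueError("prem-specific block edges may not be self-pairs")


class SynthDataset(NamedTuple):
    features: FeatureMatrix
    metadata: pd.DataFrame
    blocks: BlockAnnotation
    truth: GroundTruth


def _random_tree(k: int, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Uniform-ish random labelled tree on k nodes (random attachment)."""
    order = rng.permutation(k)
    edges: set[tuple[int, int]] = set()
    for i in range(1, k):
        child = int(order[i])
        parent = int(order[int(rng.integers(0, i))])
        edges.add(tuple(sorted((parent, child))))  # type: ignore[arg-type]
    return edges


def _rewire_tree(
    tree: set[tuple[int, int]], n_rewire: int, k: int, rng: np.random.Generator
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Rewire up to ``n_rewire`` leaves of a spanning tree onto a hub.

    A hub node is drawn at random; leaves of the original tree (not
    already adjacent to the hub) are detached from their parent and
    attached directly to the hub, keeping a spanning tree.  Returns
    (rewired tree, the set of new leaf-hub edges).  The new edges never
    coincide with original edges, so the difference rewired-minus-
    original is exactly the new set — a hub-and-spokes reorganization
    of the dependence structure, as one latent severity axis would
    induce.
    """
    if n_rewire == 0:
        return set(tree), set()
    if n_rewire >= k - 1:
        # full reorganization: an independent spanning tree, edge-disjoint
        # from the original, with node degrees capped at 3 (low degrees
        # keep every edge estimable as a partial correlation)
        for _attempt in range(500):
            order = list(rng.permutation(k))
            deg = [0] * k
            edges: set[tuple[int, int]] = set()
            ok = True
            for i in range(1, k):
                child = int(order[i])
                cands = [
                    int(order[j])
                    for j in range(i)
                    if deg[int(order[j])] < 3
                    and tuple(sorted((child, int(order[j])))) not in tree
                ]
                if not cands:
                    ok = False
                    break
                parent = int(rng.choice(cands))
                deg[parent] += 1
                deg[child] += 1
                edges.add(tuple(sorted((child, parent))))  # type: ignore[arg-type]
            if ok:
                return edges, set(edges)
        # tiny k can make the disjoint capped tree infeasible; fall through
    edge_list = sorted(tree)
    removed_idx = rng.choice(len(edge_list), size=n_rewire, replace=False)
    removed = {edge_list[int(i)] for i in removed_idx}
    kept = set(tree) - removed
    comp = list(range(k))

    def find(a: int) -> int:
        while comp[a] != a:
            comp[a] = comp[comp[a]]
            a = comp[a]
        return a

    for a, b in kept:
        comp[find(a)] = find(b)
    new_edges: set[tuple[int, int]] = set()
    while True:
        roots = sorted({find(i) for i in range(k)})
        if len(roots) == 1:
            break
        members: dict[int, list[int]] = {}
        for i in range(k):
            members.setdefault(find(i), []).append(i)
        for _attempt in range(1000):
            ra, rb = rng.choice(roots, size=2, replace=False)
            a = int(rng.choice(members[int(ra)]))
            b = int(rng.choice(members[int(rb)]))
            pair = tuple(sorted((a, b)))
            if pair not in tree and pair not in new_edges:
                new_edges.add(pair)  # type: ignore[arg-type]
                comp[find(a)] = find(b)
                break
        else:  # pragma: no cover - only reachable for tiny pathological k
            raise RuntimeError("could not rewire the block tree")
    return kept | new_edges, new_edges


def _wire_factors(
    mat: np.ndarray, tree: set[tuple[int, int]], rho: float
) -> np.ndarray:
    """Correlate iid factor columns along a spanning tree (BFS propagation)."""
    k = mat.shape[1]
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    for a, b in tree:
        adj[a].append(b)
        adj[b].append(a)
    out = mat.copy()
    seen = {0}
    queue = [0]
    while queue:
        parent = queue.pop(0)
        for child in adj[parent]:
            if child in seen:
                continue
            seen.add(child)
            out[:, child] = rho * out[:, parent] + np.sqrt(1 - rho**2) * out[:, child]
            queue.append(child)
    return out


def _log_sds(config: SynthConfig) -> tuple[float, float]:
    """Latent-factor and noise SDs (log scale) realizing the target correlation.

    With metabolite log-intensity = s*z_block + tau*eps, the within-block
    pairwise |correlation| is s^2 / (s^2 + tau^2) = within_block_rho.
    """
    tau = float(np.sqrt(np.log1p(config.noise_cv**2)))
    rho = config.within_block_rho
    s = tau * float(np.sqrt(rho / (1.0 - rho))) if rho > 0 else 0.0
    return s, tau


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Draw a dataset from the generative model.

    Per sample i and metabolite j:

    ``x_ij = m_j * exp(s * zbar_ij) * 2^(fc_j * I[i in Prem]) * d_i * exp(tau * e_ij)``

    where ``m_j`` is a log-normal baseline median, ``zbar_ij`` combines
    the (signed-loading) latent factors of j's blocks, ``d_i`` is the
    log-normal dilution factor, and ``e_ij`` is standard normal
    measurement noise.  Identical config (including seed) gives
    identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_latent, rng_noise, rng_meta = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]

    n = config.n_term + config.n_prem
    sample_ids = [f"Term{i+1:03d}" for i in range(config.n_term)] + [
        f"Prem{i+1:03d}" for i in range(config.n_prem)
    ]
    groups = np.array(["Term"] * config.n_term + ["Prem"] * config.n_prem)
    is_prem = groups == "Prem"
    met_ids = [f"M{j+1:03d}" for j in range(config.n_metabolites)]
    block_ids = [f"B{k+1:02d}" for k in range(config.n_blocks)]
    k_blocks = config.n_blocks

    # --- block membership: 1..max blocks per metabolite, without replacement
    membership: dict[str, tuple[str, ...]] = {}
    member_idx: list[np.ndarray] = []
    # most metabolites map to a single function; secondary/tertiary
    # annotations are the exception, as in curated function databases.
    # A round-robin over a random metabolite order guarantees every block
    # at least ceil(m / k) >= 3 primary members at the default dimensions,
    # so no block is lost to the <3-member filter.
    multi_p = np.array([0.8, 0.15, 0.05][: config.max_blocks_per_metabolite])
    multi_p = multi_p / multi_p.sum()
    met_order = rng_design.permutation(config.n_metabolites)
    block_order = rng_design.permutation(k_blocks)
    primary_of = np.empty(config.n_metabolites, dtype=int)
    for pos, j in enumerate(met_order):
        primary_of[j] = int(block_order[pos % k_blocks])
    for j, met in enumerate(met_ids):
        k = 1 + int(rng_design.choice(len(multi_p), p=multi_p))
        k = min(k, k_blocks)
        primary = primary_of[j]
        others = [b for b in range(k_blocks) if b != primary]
        extra = rng_design.choice(len(others), size=k - 1, replace=False)
        chosen = np.array([primary] + [others[int(e)] for e in extra])
        membership[met] = tuple(block_ids[c] for c in chosen)
        member_idx.append(chosen)

    # --- inter-block wiring: a shared spanning tree, rewired in Prem
    term_tree = _random_tree(k_blocks, rng_design)
    prem_tree, new_edges = _rewire_tree(
        term_tree, config.n_prem_specific_edges, k_blocks, rng_design
    )
    edges: set[tuple[str, str]] = {
        tuple(sorted((block_ids[a], block_ids[b]))) for a, b in new_edges  # type: ignore[misc]
    }

    # --- hot blocks concentrate the differential metabolites
    n_hot = int(round(config.frac_hot_blocks * k_blocks))
    hot = set(int(b) for b in rng_design.permutation(k_blocks)[:n_hot])

    n_diff = int(round(config.frac_differential * config.n_metabolites))
    flags = np.zeros(config.n_metabolites, dtype=bool)
    fc = np.zeros(config.n_metabolites)
    if n_diff > 0:
        # anchor differential metabolites: every block keeps a few
        # dysregulated primary members (function-level dysregulation is
        # never entirely absent), then the remainder concentrates in the
        # hot blocks
        primary_members: dict[int, list[int]] = {}
        for j, chosen in enumerate(member_idx):
            primary_members.setdefault(int(chosen[0]), []).append(j)
        pools = {
            k: list(rng_design.permutation(v)) for k, v in primary_members.items()
        }
        chosen_set: set[int] = set()
        anchors: list[int] = []
        # round-robin so the anchor budget spreads evenly over blocks
        for _round in range(config.min_anchor_per_block):
            for k in range(k_blocks):
                if len(chosen_set) >= n_diff:
                    break
                pool = pools.get(k, [])
                if pool:
                    j = int(pool.pop())
                    chosen_set.add(j)
                    anchors.append(j)
        remaining = [j for j in range(config.n_metabolites) if j not in chosen_set]
        n_more = n_diff - len(chosen_set)
        if n_more > 0 and remaining:
            weights = np.array(
                [
                    config.hot_block_boost
                    if any(int(c) in hot for c in member_idx[j])
                    else 1.0
                    for j in remaining
                ]
            )
            probs = weights / weights.sum()
            more = rng_design.choice(
                len(remaining), size=min(n_more, len(remaining)), replace=False, p=probs
            )
            chosen_set.update(remaining[int(i)] for i in more)
        which = np.array(sorted(chosen_set))
        n_diff = len(which)
        flags[which] = True
        # differential metabolites are function-specific markers: they
        # keep only their primary annotation, so their (strong) columns
        # cannot couple unrelated blocks
        for j in which:
            if len(member_idx[j]) > 1:
                member_idx[j] = member_idx[j][:1]
                membership[met_ids[j]] = (block_ids[int(member_idx[j][0])],)
        # signs balance ~50/50 *within* each block (and hence globally):
        # a block's intensity then shifts its members symmetrically and
        # leaves the per-sample median quotient (PQN) untouched
        sign_by_met: dict[int, float] = {}
        by_primary: dict[int, list[int]] = {}
        for j in sorted(chosen_set):
            by_primary.setdefault(int(member_idx[j][0]), []).append(j)
        for k in sorted(by_primary):
            js = list(rng_design.permutation(by_primary[k]))
            start = int(rng_design.integers(0, 2))
            for i, j in enumerate(js):
                sign_by_met[int(j)] = 1.0 if (i + start) % 2 == 0 else -1.0
        lo, hi = config.log2fc_magnitudes
        magnitudes = rng_design.uniform(lo, hi, size=n_diff)
        # the largest magnitudes go to the hot blocks' anchors (the
        # strongly dysregulated functions), then to the other blocks'
        # lead markers, then to the remaining differential metabolites
        order = np.argsort(magnitudes)[::-1]
        hot_anchors = [j for j in anchors if int(member_idx[j][0]) in hot]
        cold_anchors = [j for j in anchors if j not in set(hot_anchors)]
        ordered_mets = (
            hot_anchors
            + cold_anchors
            + [j for j in which if j not in set(anchors)]
        )
        mag_by_met = {met: magnitudes[order[i]] for i, met in enumerate(ordered_mets)}
        for j in which:
            fc[j] = sign_by_met[j] * mag_by_met[j]

    # --- latent layers: activity z (class-independent, within-block
    #     correlation) and wiring factor v (per-block expression intensity,
    #     correlated along the group's tree)
    z = rng_latent.standard_normal((n, k_blocks))
    v = rng_latent.standard_normal((n, k_blocks))
    rho = config.block_edge_rho
    if rho > 0:
        v[~is_prem] = _wire_factors(v[~is_prem], term_tree, rho)
        v[is_prem] = _wire_factors(v[is_prem], prem_tree, rho)

    s, tau = _log_sds(config)
    zbar = np.zeros((n, config.n_metabolites))
    vbar = np.zeros((n, config.n_metabolites))
    for j, chosen in enumerate(member_idx):
        zbar[:, j] = z[:, chosen].sum(axis=1) / np.sqrt(len(chosen))
        # effect modulation acts through the metabolite's primary function
        # only, keeping each planted block-block edge identifiable
        vbar[:, j] = v[:, int(chosen[0])]

    baseline = np.exp(rng_design.normal(np.log(500.0), 1.0, size=config.n_metabolites))
    dilution = np.exp(rng_noise.normal(0.0, config.dilution_sd, size=n))
    noise = np.exp(tau * rng_noise.standard_normal((n, config.n_metabolites)))

    # realized effect along the fold-change pattern: the planted group
    # shift fc_j plus a per-sample modulation by the block's expression
    # intensity (zero mean in both groups, so group-mean log2 fold
    # changes match the planted values exactly)
    fc_nats = fc * np.log(2.0)
    prem_col = is_prem.astype(float)[:, None]
    effect = fc_nats[None, :] * (prem_col + config.severity_sd * vbar)
    x = (
        baseline[None, :]
        * np.exp(s * zbar + effect)
        * dilution[:, None]
        * noise
    )

    features = FeatureMatrix(
        pd.DataFrame(x, index=pd.Index(sample_ids, name="sample_id"), columns=met_ids),
        state="raw",
    )
    metadata = pd.DataFrame(
        {
            "group": groups,
            # neutral covariate, independent of all planted structure
            "sex": rng_meta.choice(["F", "M"], size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        differential_flags=pd.Series(flags, index=met_ids, name="differential"),
        planted_log2fc=pd.Series(fc, index=met_ids, name="log2fc"),
        block_membership=membership,
        prem_specific_block_edges=edges,
        dilution_factors=pd.Series(dilution, index=sample_ids, name="dilution"),
    )
    return SynthDataset(features, metadata, BlockAnnotation(membership), truth)


def write_fixtures(dataset: SynthDataset, directory: str | Path, truth: bool = True) -> list[Path]:
    """Write features.csv, metadata.csv, blocks.csv (and truth.json).

    The CSV dialects round-trip losslessly through the readers in
    :mod:`metabloc.pipeline` (full float repr, no compression).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    f = directory / "features.csv"
    dataset.features.data.to_csv(f, float_format="%.17g")
    written.append(f)

    m = directory / "metadata.csv"
    dataset.metadata.to_csv(m)
    written.append(m)

    b = directory / "blocks.csv"
    dataset.blocks.to_frame().to_csv(b, index=False)
    written.append(b)

    if truth:
        t = directory / "truth.json"
        payload = {
            "differential_flags": {
                k: bool(v) for k, v in dataset.truth.differential_flags.items()
            },
            "planted_log2fc": {k: float(v) for k, v in dataset.truth.planted_log2fc.items()},
            "block_membership": {k: list(v) for k, v in dataset.truth.block_membership.items()},
            "prem_specific_block_edges": sorted(
                list(pair) for pair in dataset.truth.prem_specific_block_edges
            ),
            "dilution_factors": {
                k: float(v) for k, v in dataset.truth.dilution_factors.items()
            },
        }
        t.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(t)
    return written


def read_truth(path: str | Path) -> GroundTruth:
    """Load a truth.json written by :func:`write_fixtures`."""
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        differential_flags=pd.Series(payload["differential_flags"], name="differential"),
        planted_log2fc=pd.Series(payload["planted_log2fc"], name="log2fc"),
        block_membership={k: tuple(v) for k, v in payload["block_membership"].items()},
        prem_specific_block_edges={tuple(p) for p in payload["prem_specific_block_edges"]},
        dilution_factors=pd.Series(payload["dilution_factors"], name="dilution"),
    )
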