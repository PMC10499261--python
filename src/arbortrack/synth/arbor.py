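"""Ground-truth arbor geometries.

Generates sparsely branched tubular arbors of the kind a taste ganglion
neuron extends into a taste bud: a single stem entering from the floor of
the imaging volume (the basement membrane side), rising into the bud and
branching into a requested number of terminal branches. Dimensions are in
μm; radii follow the sub-micrometre calibre of these fibres (~0.3–0.5 μm).
"""

from __future__ import annotations

import numpy as np

from arbortrack.skeleton import SkeletonNode, SkeletonTree

__all__ = ["make_arbor_skeleton", "grow_path", "sample_branch_direction"]

STEP_UM = 1.0  # polyline sampling step
STEM_RADIUS_UM = 0.5
BRANCH_RADIUS_UM = 0.4


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _jitter_direction(rng: np.random.Generator, d: np.ndarray, sigma: float) -> np.ndarray:
    return _unit(d + rng.normal(0.0, sigma, size=3))


def sample_branch_direction(
    rng: np.random.Generator,
    parent_dir: np.ndarray,
    existing: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    n_candidates: int = 8,
    lookahead_um: float = 3.0,
) -> np.ndarray:
    """Pick a direction diverging 40–80° from ``parent_dir``.

    When existing node positions are supplied, several candidates are drawn
    and the one whose lookahead point lies farthest from the existing arbor
    is kept, which keeps sibling branches spatially separable at imaging
    resolution.
    """
    best, best_score = None, -np.inf
    for _ in range(n_candidates):
        angle = np.deg2rad(rng.uniform(40.0, 80.0))
        # random vector perpendicular to parent_dir
        perp = _unit(np.cross(parent_dir, rng.normal(size=3)))
        cand = _unit(np.cos(angle) * parent_dir + np.sin(angle) * perp)
        if existing is None or origin is None or len(existing) == 0:
            return cand
        probe = origin + lookahead_um * cand
        score = np.min(np.linalg.norm(existing - probe, axis=1))
        if score > best_score:
            best, best_score = cand, score
    return best


def grow_path(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    extent_um: np.ndarray,
    margin_um: float = 1.5,
    wiggle: float = 0.15,
    avoid: np.ndarray | None = None,
    min_sep_um: float = 4.0,
    free_radius_um: float = 4.0,
) -> np.ndarray:
    """Random-walk polyline of ``length_um`` from ``start`` (excluded), kept
    inside ``[margin, extent - margin]`` by reflecting the heading at walls.

    When ``avoid`` points are given, each step steers clear of them (beyond
    ``free_radius_um`` of the start, so the attachment region is exempt):
    branches that approach closer than ``min_sep_um`` would fuse at imaging
    resolution once rendered and blurred.
    """
    n_steps = max(1, int(round(length_um / STEP_UM)))
    pts = np.empty((n_steps, 3))
    pos = np.asarray(start, dtype=float).copy()
    d = _unit(np.asarray(direction, dtype=float))
    lo = np.full(3, margin_um)
    hi = np.asarray(extent_um, dtype=float) - margin_um
    if avoid is not None and len(avoid):
        keep = np.linalg.norm(avoid - pos, axis=1) > free_radius_um
        avoid = avoid[keep]
        if len(avoid) == 0:
            avoid = None
    for k in range(n_steps):
        base_d = d
        best, best_clear = None, -np.inf
        for trial in range(8):
            cand = _jitter_direction(rng, base_d, wiggle if trial == 0 else 0.45)
            nxt = pos + STEP_UM * cand
            for ax in range(3):
                if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                    cand[ax] = -cand[ax]
            nxt = np.clip(pos + STEP_UM * cand, lo, hi)
            if avoid is None:
                best, best_nxt = cand, nxt
                break
            clear = np.min(np.linalg.norm(avoid - nxt, axis=1))
            if clear > best_clear:
                best, best_nxt, best_clear = cand, nxt, clear
            if clear >= min_sep_um:
                break
        d = best
        pos = best_nxt
        pts[k] = pos
    return pts


def make_arbor_skeleton(
    seed: int | np.random.Generator,
    n_terminal: int,
    extent_um: tuple[float, float, float] = (30.0, 30.0, 40.0),
    stem_fraction: float = 0.3,
    branch_length_range_um: tuple[float, float] = (8.0, 16.0),
) -> SkeletonTree:
    """Generate a synthetic arbor with exactly ``n_terminal`` terminal branches.

    A straight-ish stem enters from the volume floor (z = 0) and climbs to
    ``stem_fraction`` of the volume height; the first terminal path continues
    from the stem tip, and further branches sprout from random interior nodes
    of the arbor until the requested number of leaves is reached.

    Parameters
    ----------
    seed : int or Generator
        Randomness source; the same seed reproduces the same tree.
    n_terminal : int
        Number of leaf-terminating branches (≥ 1).
    extent_um : 3-tuple
        Volume extents (x, y, z) in μm; all positive.
    """
    if n_terminal < 1:
        raise ValueError(f"n_terminal must be ≥ 1, got {n_terminal}")
    extent = np.asarray(extent_um, dtype=float)
    if extent.shape != (3,) or np.any(extent <= 0):
        raise ValueError(f"extent_um must be 3 positive lengths, got {extent_um}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nodes: list[SkeletonNode] = []
    positions: list[np.ndarray] = []
    dist_to_tip: dict[int, float] = {}  # arc distance to the tip of a node's own path
    used_attachments: list[np.ndarray] = []

    def add_node(pos: np.ndarray, radius: float, parent: int | None) -> int:
        nid = len(nodes) + 1
        nodes.append(SkeletonNode(nid, pos, radius, parent))
        positions.append(np.asarray(pos, dtype=float))
        return nid

    # Stem: enters at the floor near the volume centre, climbs in +z.
    base = np.array(
        [extent[0] / 2 + rng.normal(0, 1.0), extent[1] / 2 + rng.normal(0, 1.0), 0.0]
    )
    base[:2] = np.clip(base[:2], 2.0, extent[:2] - 2.0)
    root_id = add_node(base, STEM_RADIUS_UM, None)
    stem_height = stem_fraction * extent[2]
    stem_pts = grow_path(rng, base, np.array([0.0, 0.0, 1.0]), stem_height, extent, wiggle=0.05)
    last = root_id
    for p in stem_pts:
        last = add_node(p, STEM_RADIUS_UM, last)
    stem_tip = last
    stem_node_ids = set(range(1, stem_tip + 1))

    # First terminal path continues upward from the stem tip.
    def grow_terminal(from_id: int, direction: np.ndarray) -> None:
        length = rng.uniform(*branch_length_range_um)
        pts = grow_path(
            rng,
            nodes[from_id - 1].position,
            direction,
            length,
            extent,
            avoid=np.array(positions),
        )
        parent = from_id
        ids = []
        for p in pts:
            parent = add_node(p, BRANCH_RADIUS_UM, parent)
            ids.append(parent)
        for k, nid in enumerate(ids):
            dist_to_tip[nid] = STEP_UM * (len(ids) - 1 - k)

    grow_terminal(stem_tip, _unit(np.array([rng.normal(0, 0.3), rng.normal(0, 0.3), 1.0])))

    # Remaining branches sprout from interior arbor nodes (never from tips,
    # which would extend a branch instead of adding one).
    for _ in range(n_terminal - 1):
        tree_tmp_children: dict[int, int] = {}
        for n in nodes:
            if n.parent is not None:
                tree_tmp_children[n.parent] = tree_tmp_children.get(n.parent, 0) + 1
        candidates = [
            n.id
            for n in nodes
            if n.id not in stem_node_ids
            and tree_tmp_children.get(n.id, 0) == 1  # interior, not yet a fork
            and n.position[2] > stem_height * 0.8
            # keep branch points clear of tips (no sub-resolution terminal
            # stubs) and of each other (junctions resolvable after blurring)
            # an attachment subdivides the host path: the distal remainder
            # becomes that leaf's terminal branch, so keep it resolvable
            and dist_to_tip.get(n.id, np.inf) >= 6.0
            and all(
                np.linalg.norm(n.position - a) >= 3.0 for a in used_attachments
            )
        ]
        if not candidates:
            candidates = [stem_tip]
        attach = int(rng.choice(candidates))
        used_attachments.append(nodes[attach - 1].position.copy())
        node = nodes[attach - 1]
        parent_dir = (
            _unit(node.position - nodes[node.parent - 1].position)
            if node.parent is not None
            else np.array([0.0, 0.0, 1.0])
        )
        d = sample_branch_direction(
            rng, parent_dir, existing=np.array(positions), origin=node.position
        )
        # bias away from the floor so branches stay in the bud region
        d = _unit(d + np.array([0.0, 0.0, 0.35]))
        grow_terminal(attach, d)

    return SkeletonTree(nodes)
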