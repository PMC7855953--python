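"""Partner-specific interface prediction by 2D cross-correlation of face grids.

Each protein is reduced to six 2D property grids (one per face). Every pair
of faces — 36 pairs — is scored by a full (zero-padded) 2D cross-correlation
at every lag and at every in-plane rotation of the partner grid, for the
unrotated and the 45°/45°-rotated K-means initializations. Complementarity
convention: hydrophobicity and conservation are ranked by maximum score;
charge by minimum (opposite signs multiply to negative values, so the most
negative placement is the most complementary). A prediction is *consistent*
when all top-m placements involve the same two faces; the winning placement
is mapped back through the bin -> atom maps to residue sets on both partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import Config, PropertiedStructure
from .surface import (FaceGrid, FaceSegmentation, SurfaceModel, build_face_grids,
                      biased_kmeans_faces, compute_surface_points, orient_pca,
                      residue_depth, rotate_structure)

logger = logging.getLogger(__name__)

#: properties ranked by maximum score; charge is ranked by minimum.
MAX_TYPE_PROPERTIES = {"hydrophobicity", "conservation"}

INIT_UNROTATED = "unrotated"
INIT_ROTATED = "rotated45"


@dataclass(frozen=True)
class CorrelationHit:
    """One scored placement of a face of B against a face of A."""

    face_a: int
    face_b: int
    rotation_deg: int
    lag: tuple[int, int]          # (row, col) offset of B's grid relative to A's
    score: float
    property: str
    initialization: str


@dataclass
class PropertyResult:
    """Per-property outcome: ranked hits of the chosen initialization."""

    property: str
    initialization: str
    hits: list[CorrelationHit]
    top_hits: list[CorrelationHit]
    consistent: bool
    face_pair: tuple[int, int]


@dataclass
class PreparedInit:
    """One K-means initialization: oriented coordinates, faces, grids."""

    structure: PropertiedStructure
    segmentation: FaceSegmentation
    grids: dict[str, list[FaceGrid]]


@dataclass
class PreparedProtein:
    structure: PropertiedStructure        # after optional PCA orientation
    surface: SurfaceModel
    inits: dict[str, PreparedInit]


@dataclass
class InterfacePrediction:
    residues_a: set[tuple[str, str]]
    residues_b: set[tuple[str, str]]
    winning_hit: CorrelationHit
    consistent: bool
    property_used: str
    all_top_hits: list[CorrelationHit]
    initialization: str
    property_results: dict[str, PropertyResult]
    prepared_a: PreparedProtein
    prepared_b: PreparedProtein


# ---------------------------------------------------------------------------
# Cross-correlation core


def cross_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full zero-padded 2D cross-correlation by direct summation.

    Output C has shape (Ra+Rb-1, Ca+Cb-1); C[k, l] is the sum over
    overlapping cells of a·b when b is offset by lag
    (k - Rb + 1, l - Cb + 1) relative to a (b[i, j] over a[i+dr, j+dc]).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rb, cb = b.shape
    a_pad = np.pad(a, ((rb - 1, rb - 1), (cb - 1, cb - 1)))
    win = sliding_window_view(a_pad, (rb, cb))
    return np.einsum("klij,ij->kl", win, b)


def lag_of_index(k: int, l: int, b_shape: tuple[int, int]) -> tuple[int, int]:
    """Convert a correlation-matrix index to the (row, col) lag of B vs A."""
    return k - b_shape[0] + 1, l - b_shape[1] + 1


# ---------------------------------------------------------------------------
# Grid rotation (nearest-neighbour, exact at multiples of 90°)


@dataclass
class RotatedGrid:
    """A face grid resampled at an in-plane rotation, with a cell back-map."""

    values: np.ndarray
    occupancy: np.ndarray
    cell_map: np.ndarray          # (R', C', 2) source cell of each output cell; -1 if none
    angle_deg: int
    source: FaceGrid


def rotation_cell_map(shape: tuple[int, int], angle_deg: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour cell map for a counter-clockwise grid rotation.

    Returns (cell_map, valid): cell_map[i, j] is the (row, col) source cell
    feeding output cell (i, j), and valid marks output cells that fall inside
    the source grid. Multiples of 90° are exact cell permutations.
    """
    r, c = shape
    angle = int(round(angle_deg)) % 360
    if angle % 90 == 0:
        k = angle // 90
        rows, cols = np.indices((r, c))
        mr = np.rot90(rows, k)
        mc = np.rot90(cols, k)
        cell_map = np.stack([mr, mc], axis=-1)
        return cell_map, np.ones(mr.shape, dtype=bool)
    theta = np.radians(angle)
    cos, sin = np.cos(theta), np.sin(theta)
    fwd = np.array([[cos, -sin], [sin, cos]])      # acts on (d_row, d_col)
    corners = np.array([[0, 0], [0, c], [r, 0], [r, c]], dtype=float)
    center = np.array([r / 2, c / 2])
    rot_corners = (corners - center) @ fwd.T
    span = rot_corners.max(axis=0) - rot_corners.min(axis=0)
    out_r = max(1, int(np.ceil(span[0] - 1e-9)))
    out_c = max(1, int(np.ceil(span[1] - 1e-9)))
    out_center = np.array([out_r / 2, out_c / 2])
    oi, oj = np.indices((out_r, out_c))
    d_out = np.stack([oi + 0.5, oj + 0.5], axis=-1) - out_center
    inv = np.array([[cos, sin], [-sin, cos]])
    d_in = d_out @ inv.T + center
    src = np.floor(d_in).astype(int)
    valid = ((src[..., 0] >= 0) & (src[..., 0] < r)
             & (src[..., 1] >= 0) & (src[..., 1] < c))
    src[~valid] = -1
    return src, valid


def rotate_grid(grid: FaceGrid, angle_deg: float) -> RotatedGrid:
    """Rotate a face grid about its centre (values and occupancy together)."""
    cell_map, valid = rotation_cell_map(grid.shape, angle_deg)
    values = np.zeros(valid.shape)
    occupancy = np.zeros(valid.shape, dtype=bool)
    mr, mc = cell_map[..., 0], cell_map[..., 1]
    values[valid] = grid.values[mr[valid], mc[valid]]
    occupancy[valid] = grid.occupancy[mr[valid], mc[valid]]
    values[~occupancy] = 0.0
    return RotatedGrid(values=values, occupancy=occupancy, cell_map=cell_map,
                       angle_deg=int(round(angle_deg)) % 360, source=grid)


# ---------------------------------------------------------------------------
# Scoring


def hit_sort_key(hit: CorrelationHit):
    primary = hit.score if hit.property == "charge" else -hit.score
    return (primary, hit.face_a, hit.face_b, hit.rotation_deg, hit.lag)


def score_all_pairs(grids_a: Sequence[FaceGrid], grids_b: Sequence[FaceGrid],
                    property_name: str, config: Config,
                    initialization: str = INIT_UNROTATED,
                    rotations_b: Mapping[tuple[int, int], RotatedGrid] | None = None,
                    ) -> list[CorrelationHit]:
    """Rank every (face pair, rotation, lag) placement for one property.

    Ascending score for charge (most negative first), descending otherwise;
    ties broken lexicographically by (face_a, face_b, rotation, lag). Lags
    with fewer than ``min_overlap_bins`` co-occupied cells are excluded. Per
    (pair, rotation) only the best ``top_m`` lags are retained, which is
    sufficient for initialization selection and the consistency rule.
    """
    angles = range(0, 360, config.rotation_step_deg)
    if rotations_b is None:
        rotations_b = {(g.face_id, ang): rotate_grid(g, ang)
                       for g in grids_b for ang in angles}
    sign = 1.0 if property_name == "charge" else -1.0  # minimize sign*score
    hits: list[CorrelationHit] = []
    for ga in grids_a:
        occ_a = ga.occupancy.astype(float)
        for gb in grids_b:
            for ang in angles:
                rb = rotations_b[(gb.face_id, ang)]
                overlap = np.rint(cross_correlate(occ_a, rb.occupancy.astype(float)))
                mask = overlap >= config.min_overlap_bins
                if not mask.any():
                    continue
                scores = cross_correlate(ga.values, rb.values)
                flat_idx = np.flatnonzero(mask.ravel())
                flat_scores = sign * scores.ravel()[flat_idx]
                if len(flat_idx) > config.top_m:
                    part = np.argpartition(flat_scores, config.top_m - 1)[:config.top_m]
                    flat_idx, flat_scores = flat_idx[part], flat_scores[part]
                for idx, s in zip(flat_idx, flat_scores):
                    k, l = divmod(int(idx), scores.shape[1])
                    hits.append(CorrelationHit(
                        face_a=ga.face_id, face_b=gb.face_id, rotation_deg=ang,
                        lag=lag_of_index(k, l, rb.values.shape),
                        score=float(sign * s), property=property_name,
                        initialization=initialization))
    hits.sort(key=hit_sort_key)
    return hits


def select_initialization(hits_init1: list[CorrelationHit],
                          hits_init2: list[CorrelationHit],
                          property_name: str, top_m: int = 10
                          ) -> tuple[str, list[CorrelationHit]]:
    """Pick the start position whose top-m score sum is best; ties -> unrotated."""
    if not hits_init2:
        return INIT_UNROTATED, hits_init1
    if not hits_init1:
        return INIT_ROTATED, hits_init2
    m = min(top_m, len(hits_init1), len(hits_init2))
    s1 = sum(h.score for h in hits_init1[:m])
    s2 = sum(h.score for h in hits_init2[:m])
    if property_name == "charge":
        return (INIT_ROTATED, hits_init2) if s2 < s1 else (INIT_UNROTATED, hits_init1)
    return (INIT_ROTATED, hits_init2) if s2 > s1 else (INIT_UNROTATED, hits_init1)


def consistency_check(top_hits: Sequence[CorrelationHit]
                      ) -> tuple[bool, tuple[int, int]]:
    """Consistent iff all top hits share one face pair; else the modal pair.

    Modal ties are broken by the earliest-ranked occurrence.
    """
    if not top_hits:
        raise ValueError("no hits to check")
    pairs = [(h.face_a, h.face_b) for h in top_hits]
    first = pairs[0]
    if all(p == first for p in pairs):
        return True, first
    counts: dict[tuple[int, int], int] = {}
    for p in pairs:
        counts[p] = counts.get(p, 0) + 1
    best = max(counts.values())
    modal = next(p for p in pairs if counts[p] == best)
    return False, modal


# ---------------------------------------------------------------------------
# Mapping a placement back to residues


def extract_interface(hit: CorrelationHit, grid_a: FaceGrid, grid_b: FaceGrid,
                      structure_a: PropertiedStructure,
                      structure_b: PropertiedStructure
                      ) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Residues of both partners under the overlapping occupied cells at the
    hit's lag, with B's atoms traced back through the rotation's cell map."""
    rb = rotate_grid(grid_b, hit.rotation_deg)
    dr, dc = hit.lag
    ra_dim, ca_dim = grid_a.shape
    atoms_a: list[int] = []
    atoms_b: list[int] = []
    for ib in range(rb.values.shape[0]):
        ia = ib + dr
        if ia < 0 or ia >= ra_dim:
            continue
        for jb in range(rb.values.shape[1]):
            ja = jb + dc
            if ja < 0 or ja >= ca_dim:
                continue
            if not (grid_a.occupancy[ia, ja] and rb.occupancy[ib, jb]):
                continue
            atoms_a.extend(grid_a.bin_atoms[(ia, ja)])
            src = tuple(int(v) for v in rb.cell_map[ib, jb])
            atoms_b.extend(grid_b.bin_atoms[src])
    if not atoms_a or not atoms_b:
        raise ValueError("empty interface: no occupied overlap at the hit's lag")
    res_a = {structure_a.residue_of(i) for i in atoms_a}
    res_b = {structure_b.residue_of(i) for i in atoms_b}
    return res_a, res_b


# ---------------------------------------------------------------------------
# Orchestration


def prepare_protein(structure: PropertiedStructure, properties: Sequence[str],
                    config: Config) -> PreparedProtein:
    """Surface, faces and grids for both K-means initializations.

    The accessible surface and residue depths are rotation-invariant, so they
    are computed once; the 45°/45° re-initialization only re-segments and
    re-projects the (rigidly rotated) surface atoms.
    """
    for prop in properties:
        vals = structure.property_values(prop)[structure.heavy_mask()]
        if np.isnan(vals).any():
            raise ValueError(
                f"property {prop!r} is not populated on all heavy atoms of "
                f"{structure.label}; cannot predict on it")
    st = orient_pca(structure) if config.use_pca_orientation else structure
    points = compute_surface_points(st, config.probe_radius, config.n_sphere_points)
    surf = residue_depth(st, points, config.depth_cutoff)
    logger.info("%s: %d surface points, %d surface atoms", st.label,
                len(points), len(surf.surface_atoms))
    init_tag = "pca_then_axis_extremes" if config.use_pca_orientation else "axis_extremes"
    inits: dict[str, PreparedInit] = {}
    for name, rotated in ((INIT_UNROTATED, st),
                          (INIT_ROTATED, rotate_structure(st, *config.reinit_angles_deg))):
        tag = init_tag if name == INIT_UNROTATED else "axis_extremes_rotated45"
        seg = biased_kmeans_faces(rotated.coords()[surf.surface_atoms],
                                  k=config.k_faces, initialization=tag)
        grids = build_face_grids(rotated, seg, surf.surface_atoms, properties, config)
        inits[name] = PreparedInit(structure=rotated, segmentation=seg, grids=grids)
        logger.info("%s/%s: face sizes %s", st.label, name,
                    np.bincount(seg.labels)[1:].tolist())
    return PreparedProtein(structure=st, surface=surf, inits=inits)


def _ordered_properties(requested: Sequence[str], config: Config) -> list[str]:
    ordered = [p for p in config.property_order if p in requested]
    ordered += [p for p in requested if p not in ordered]
    return ordered


def predict_interface(structure_a: PropertiedStructure,
                      structure_b: PropertiedStructure,
                      properties: str | Sequence[str],
                      config: Config | None = None,
                      exclude_pairs: frozenset[tuple[int, int]] = frozenset(),
                      prepared: tuple[PreparedProtein, PreparedProtein] | None = None,
                      ) -> InterfacePrediction:
    """Run the full partner-specific prediction pipeline.

    For each property: score all 36 face pairs over all in-plane rotations
    and lags for both initializations, keep the initialization with the best
    top-m score sum, and apply the consistency rule. The final prediction is
    the first consistent property (in ``config.property_order``); in antibody
    mode the top charge hit is used regardless of consistency; if no property
    is consistent, the property with the largest top |score| supplies its
    modal-pair top hit, flagged ``consistent=False``.

    ``exclude_pairs`` drops placements on the given face pairs before
    selection (used to extract a second interface).
    """
    config = (config or Config()).validate()
    if isinstance(properties, str):
        properties = [properties]
    props = _ordered_properties(list(properties), config)
    if prepared is not None:
        pa, pb = prepared
    else:
        pa = prepare_protein(structure_a, props, config)
        pb = prepare_protein(structure_b, props, config)
    results: dict[str, PropertyResult] = {}
    for prop in props:
        per_init: dict[str, list[CorrelationHit]] = {}
        for init in (INIT_UNROTATED, INIT_ROTATED):
            hits = score_all_pairs(pa.inits[init].grids[prop],
                                   pb.inits[init].grids[prop],
                                   prop, config, initialization=init)
            if exclude_pairs:
                hits = [h for h in hits if (h.face_a, h.face_b) not in exclude_pairs]
            per_init[init] = hits
        init, hits = select_initialization(per_init[INIT_UNROTATED],
                                           per_init[INIT_ROTATED],
                                           prop, config.top_m)
        if not hits:
            raise ValueError(f"no scored placements for property {prop!r}")
        top = hits[:config.top_m]
        consistent, pair = consistency_check(top)
        results[prop] = PropertyResult(property=prop, initialization=init,
                                       hits=hits, top_hits=top,
                                       consistent=consistent, face_pair=pair)
        logger.info("property %s: init=%s consistent=%s pair=%s top=%.4g",
                    prop, init, consistent, pair, top[0].score)

    winner, hit, consistent = _select_winner(results, props, config)
    init = results[winner].initialization
    grid_a = pa.inits[init].grids[winner][hit.face_a - 1]
    grid_b = pb.inits[init].grids[winner][hit.face_b - 1]
    res_a, res_b = extract_interface(hit, grid_a, grid_b,
                                     pa.inits[init].structure,
                                     pb.inits[init].structure)
    return InterfacePrediction(
        residues_a=res_a, residues_b=res_b, winning_hit=hit,
        consistent=consistent, property_used=winner,
        all_top_hits=results[winner].top_hits, initialization=init,
        property_results=results, prepared_a=pa, prepared_b=pb)


def _select_winner(results: dict[str, PropertyResult], props: Sequence[str],
                   config: Config) -> tuple[str, CorrelationHit, bool]:
    if config.antibody_mode and "charge" in results:
        r = results["charge"]
        return "charge", r.hits[0], r.consistent
    for prop in props:
        r = results[prop]
        if r.consistent:
            return prop, r.hits[0], True
    # no property consistent: largest |top score| supplies its modal-pair hit
    winner = max(props, key=lambda p: abs(results[p].hits[0].score))
    r = results[winner]
    hit = next(h for h in r.hits if (h.face_a, h.face_b) == r.face_pair)
    return winner, hit, False


def predict_second_interface(prediction: InterfacePrediction,
                             properties: str | Sequence[str],
                             config: Config | None = None) -> InterfacePrediction:
    """Re-run selection excluding the winning face pair (second interface)."""
    pair = (prediction.winning_hit.face_a, prediction.winning_hit.face_b)
    return predict_interface(
        prediction.prepared_a.structure, prediction.prepared_b.structure,
        properties, config, exclude_pairs=frozenset({pair}),
        prepared=(prediction.prepared_a, prediction.prepared_b))
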