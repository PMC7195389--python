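"""Cross-link distance validation: SLD, SASD and satisfaction classification.

Chemical cross-linking with DSBU (a Lys-reactive bifunctional reagent) yields
residue-pair restraints; a pair is geometrically feasible on a structure when
the solvent-accessible surface distance (SASD) between the two Cα atoms is at
most ~35 Å.  Tag-transfer (photoactivatable diazirine) links are short-range
and judged on the straight-line Cα-Cα distance (SLD) with a ~15 Å cutoff.

SASD is computed Jwalk-style: the space around the structure is voxelised, a
voxel is solvent-accessible when it lies farther than the probe-inflated van
der Waals radius from every atom, and the shortest 26-connected path through
accessible voxels is found with Dijkstra's algorithm (scipy sparse graph).
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "CrossLinkError",
    "read_crosslink_table",
    "compute_sld",
    "compute_sasd",
    "SasdCalculator",
    "classify_crosslinks",
    "DEFAULT_CUTOFFS",
]

#: satisfaction cutoffs in Å per linker chemistry ("up to ca. 35 Å" for DSBU
#: SASD; "~15 Å" Euclidean for the tag-transfer diazirine), boundary inclusive
DEFAULT_CUTOFFS = {"DSBU": 35.0, "tag-transfer": 15.0}

VDW_RADIUS = 1.8  # Å, uniform heavy-atom van der Waals radius
PROBE_RADIUS = 1.4  # Å, water probe
BURIAL_RADIUS = 5.0  # Å, max Cα-to-surface hop before an endpoint counts as buried
SLD_FEASIBLE_BAND = (27.0, 30.0)  # Å, DSBU SLD feasibility band (annotation only)


class CrossLinkError(ValueError):
    pass


def _parse_residue(value) -> int:
    """Accept plain integers or residue-letter-prefixed forms like ``K105``."""
    s = str(value).strip()
    stripped = s.lstrip("ACDEFGHIKLMNPQRSTVWYacdefghiklmnpqrstvwy")
    try:
        return int(stripped)
    except ValueError:
        raise CrossLinkError(f"cannot parse residue number from {value!r}")


def read_crosslink_table(csv_content: str) -> pd.DataFrame:
    """Parse a cross-link CSV into a table of unique, order-normalised pairs.

    Required columns: ``protein_a``, ``residue_a``, ``protein_b``,
    ``residue_b``, ``chemistry``.  Residue entries may carry a one-letter
    residue prefix (``K105``).  Duplicate pairs (order-insensitive) collapse to
    one row with a warning.
    """
    df = pd.read_csv(io.StringIO(csv_content), skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["protein_a", "residue_a", "protein_b", "residue_b", "chemistry"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CrossLinkError(f"cross-link table missing column(s): {missing}")
    rows = []
    for i, row in df.iterrows():
        try:
            ra = _parse_residue(row["residue_a"])
            rb = _parse_residue(row["residue_b"])
        except CrossLinkError as exc:
            raise CrossLinkError(f"row {i + 1}: {exc}") from exc
        if ra <= 0 or rb <= 0:
            raise CrossLinkError(f"row {i + 1}: residue numbers must be positive")
        pa, pb = str(row["protein_a"]).strip(), str(row["protein_b"]).strip()
        chem = str(row["chemistry"]).strip()
        if (pb, rb) < (pa, ra):  # canonical order, A-B == B-A
            pa, ra, pb, rb = pb, rb, pa, ra
        rows.append((pa, ra, pb, rb, chem, row.get("id", f"xl{i + 1}")))
    out = pd.DataFrame(
        rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "chemistry", "id"]
    )
    n_before = len(out)
    out = out.drop_duplicates(subset=["protein_a", "residue_a", "protein_b", "residue_b", "chemistry"])
    if len(out) < n_before:
        warnings.warn(f"collapsed {n_before - len(out)} duplicate cross-link pair(s)")
    return out.reset_index(drop=True)


def compute_sld(structure: Structure, res_a: int, res_b: int) -> float:
    """Straight-line (Euclidean) Cα-Cα distance in Å."""
    return float(np.linalg.norm(structure.ca_coord(res_a) - structure.ca_coord(res_b)))


# -- SASD ------------------------------------------------------------------

# 26-connected neighbourhood offsets, one representative per +/- pair
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
)


class SasdCalculator:
    """Voxel-grid SASD engine; build once per structure, query many pairs.

    Parameters
    ----------
    spacing :
        Grid spacing in Å (0.5-2.0).
    probe_radius, vdw_radius :
        A voxel is accessible when farther than ``probe_radius + vdw_radius``
        from every atom centre.
    margin :
        Padding beyond the structure's bounding box so paths can route around
        the surface.
    burial_radius :
        If no accessible voxel lies within this distance of an endpoint Cα the
        endpoint is considered buried (result: unreachable).
    """

    def __init__(
        self,
        structure: Structure,
        spacing: float = 1.0,
        probe_radius: float = PROBE_RADIUS,
        vdw_radius: float = VDW_RADIUS,
        margin: float = 8.0,
        burial_radius: float = BURIAL_RADIUS,
    ) -> None:
        if not (0.5 <= spacing <= 2.0):
            raise CrossLinkError(f"grid spacing {spacing} outside [0.5, 2.0] Å")
        xyz = structure.xyz
        if len(xyz) == 0:
            raise CrossLinkError("structure has no atoms")
        if len(xyz) > 1 and np.allclose(xyz, xyz[0]):
            raise CrossLinkError("degenerate structure: all atoms coincident")
        self.structure = structure
        self.spacing = float(spacing)
        self.burial_radius = float(burial_radius)
        self.exclusion = probe_radius + vdw_radius

        lo = xyz.min(axis=0) - margin
        hi = xyz.max(axis=0) + margin
        self.origin = lo
        self.shape = np.ceil((hi - lo) / spacing).astype(int) + 1

        # accessible voxel mask via nearest-atom distance
        grids = [self.origin[i] + spacing * np.arange(self.shape[i]) for i in range(3)]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        tree = cKDTree(xyz)
        dmin, _ = tree.query(pts, k=1, workers=-1)
        self.accessible = (dmin > self.exclusion).reshape(self.shape)
        self._points = pts
        self._acc_flat = self.accessible.ravel()
        self._acc_tree = cKDTree(pts[self._acc_flat])
        self._acc_indices = np.flatnonzero(self._acc_flat)
        # node numbering over accessible voxels only
        self._node_of = np.full(self._acc_flat.size, -1, dtype=np.int64)
        self._node_of[self._acc_indices] = np.arange(len(self._acc_indices))
        self._edges = self._build_edges()
        n = len(self._acc_indices)
        self._graph = coo_matrix(
            (self._edges[2], (self._edges[0], self._edges[1])), shape=(n, n)
        ).tocsr()

    def _build_edges(self):
        shape = self.shape
        acc = self.accessible
        rows, cols, data = [], [], []
        idx3 = np.indices(shape)
        for off in _OFFSETS:
            sl_src = tuple(
                slice(max(-o, 0), s - max(o, 0)) for o, s in zip(off, shape)
            )
            sl_dst = tuple(
                slice(max(o, 0), s - max(-o, 0)) for o, s in zip(off, shape)
            )
            both = acc[sl_src] & acc[sl_dst]
            if not both.any():
                continue
            src = np.ravel_multi_index(
                [idx3[i][sl_src][both] for i in range(3)], shape
            )
            dst = np.ravel_multi_index(
                [idx3[i][sl_dst][both] for i in range(3)], shape
            )
            w = self.spacing * float(np.linalg.norm(off))
            rows.append(self._node_of[src])
            cols.append(self._node_of[dst])
            data.append(np.full(len(src), w))
        rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
        cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
        data = np.concatenate(data) if data else np.array([])
        return rows, cols, data

    def endpoint_candidates(self, resnum: int) -> tuple[np.ndarray, np.ndarray] | None:
        """Accessible voxel nodes within burial radius of the Cα and their
        Euclidean hop lengths, or None if the site is buried."""
        ca = self.structure.ca_coord(resnum)
        idx = self._acc_tree.query_ball_point(ca, self.burial_radius)
        if not idx:
            return None
        idx = np.asarray(idx)
        nodes = self._node_of[self._acc_indices[idx]]
        hops = np.linalg.norm(self._points[self._acc_indices[idx]] - ca, axis=1)
        return nodes, hops

    def _distances_from(self, resnum: int) -> np.ndarray | None:
        """Dijkstra distances (incl. the Cα-to-surface hop) from a residue to
        every accessible voxel, using a virtual source node."""
        cand = self.endpoint_candidates(resnum)
        if cand is None:
            return None
        nodes, hops = cand
        n = len(self._acc_indices)
        rows, cols, data = self._edges
        aug = coo_matrix(
            (
                np.concatenate([data, hops]),
                (np.concatenate([rows, np.full(len(nodes), n)]), np.concatenate([cols, nodes])),
            ),
            shape=(n + 1, n + 1),
        ).tocsr()
        dist = dijkstra(aug, directed=False, indices=n)
        return dist[:n]

    def sasd(self, res_a: int, res_b: int) -> float:
        """SASD in Å between two residues' Cα atoms, or ``inf`` if unreachable.

        Defined as the minimum over accessible voxels v_a, v_b near the two
        Cα atoms of |Cα_A − v_a| + shortest-path(v_a, v_b) + |v_b − Cα_B|.
        """
        if res_a == res_b:
            return 0.0
        return self.sasd_many([(res_a, res_b)])[0]

    def sasd_many(self, pairs: list[tuple[int, int]]) -> list[float]:
        """SASD for many pairs, sharing one Dijkstra sweep per unique source."""
        results = np.full(len(pairs), np.nan)
        by_source: dict[int, list[int]] = {}
        cand_cache: dict[int, tuple | None] = {}
        for k, (a, b) in enumerate(pairs):
            if a == b:
                results[k] = 0.0
                continue
            by_source.setdefault(a, []).append(k)
        for src, ks in by_source.items():
            dist = self._distances_from(src)
            for k in ks:
                _, b = pairs[k]
                if b not in cand_cache:
                    cand_cache[b] = self.endpoint_candidates(b)
                cand = cand_cache[b]
                if dist is None or cand is None:
                    results[k] = np.inf
                    continue
                nodes, hops = cand
                total = dist[nodes] + hops
                best = total.min() if len(total) else np.inf
                results[k] = best if np.isfinite(best) else np.inf
        return results.tolist()


def compute_sasd(
    structure: Structure,
    res_a: int,
    res_b: int,
    spacing: float = 1.0,
    probe_radius: float = PROBE_RADIUS,
    **kwargs,
) -> float:
    """One-shot SASD; see :class:`SasdCalculator` for parameters."""
    calc = SasdCalculator(structure, spacing=spacing, probe_radius=probe_radius, **kwargs)
    return calc.sasd(res_a, res_b)


# -- classification --------------------------------------------------------


def classify_crosslinks(
    crosslinks: pd.DataFrame,
    structure: Structure,
    assignment=None,
    cutoffs: dict[str, float] | None = None,
    spacing: float = 1.0,
    calculator: SasdCalculator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify every cross-link as satisfied / violated / unevaluable.

    DSBU links are satisfied when SASD ≤ cutoff (35 Å default, boundary
    inclusive; unreachable counts as violated); tag-transfer links when the
    Euclidean Cα-Cα distance ≤ cutoff (15 Å default).  Pairs touching rebuilt
    (gap-filled) residues are flagged.  Returns the per-link table and a
    summary with satisfied/total split by intra-/inter-domain relation.
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    res_avail = set(structure.resnum[structure.ca_mask()].tolist())
    rebuilt_res = set(structure.resnum[structure.rebuilt].tolist())

    need_sasd = []
    for _, row in crosslinks.iterrows():
        if row["chemistry"] == "DSBU" and row["residue_a"] in res_avail and row["residue_b"] in res_avail:
            need_sasd.append((int(row["residue_a"]), int(row["residue_b"])))
    if calculator is None and need_sasd:
        calculator = SasdCalculator(structure, spacing=spacing)
    sasd_vals = dict(zip(need_sasd, calculator.sasd_many(need_sasd))) if need_sasd else {}

    records = []
    for _, row in crosslinks.iterrows():
        ra, rb = int(row["residue_a"]), int(row["residue_b"])
        chem = row["chemistry"]
        rec = {
            "id": row.get("id"),
            "residue_a": ra,
            "residue_b": rb,
            "chemistry": chem,
            "sld": np.nan,
            "sasd": np.nan,
            "cutoff": cutoffs.get(chem, np.nan),
            "satisfied": pd.NA,
            "status": "ok",
            "relation": pd.NA,
            "pair_label": pd.NA,
            "rebuilt": ra in rebuilt_res or rb in rebuilt_res,
            "sld_in_dsbu_band": pd.NA,
        }
        if ra not in res_avail or rb not in res_avail:
            missing = [r for r in (ra, rb) if r not in res_avail]
            warnings.warn(f"cross-link {row.get('id')}: residue(s) {missing} absent from structure")
            rec["status"] = "unevaluable"
            records.append(rec)
            continue
        sld = compute_sld(structure, ra, rb)
        rec["sld"] = sld
        rec["sld_in_dsbu_band"] = bool(sld <= SLD_FEASIBLE_BAND[1])
        if chem == "DSBU":
            sasd = sasd_vals[(ra, rb)]
            rec["sasd"] = sasd
            rec["satisfied"] = bool(np.isfinite(sasd) and sasd <= cutoffs["DSBU"])
        elif chem == "tag-transfer":
            rec["satisfied"] = bool(sld <= cutoffs["tag-transfer"])
        else:
            raise CrossLinkError(f"unknown linker chemistry {chem!r}")
        if assignment is not None:
            rec["relation"] = assignment.relation(ra, rb)
            rec["pair_label"] = assignment.pair_label(ra, rb)
        records.append(rec)

    table = pd.DataFrame(records)
    evaluable = table[table["status"] == "ok"]
    summary = {
        "total": int(len(table)),
        "evaluable": int(len(evaluable)),
        "satisfied": int(evaluable["satisfied"].sum()),
    }
    if assignment is not None and len(evaluable):
        for rel, grp in evaluable.groupby("relation"):
            summary[rel] = {"satisfied": int(grp["satisfied"].sum()), "total": int(len(grp))}
    return table, summary


def crosslinks_to_restraints(
    crosslinks: pd.DataFrame, upper: float = 27.0, lower: float = 0.0, k: float = 1.0
):
    """Export a cross-link table as flat-well restraints for the annealer."""
    from .annealing import FlatWellRestraint

    return [
        FlatWellRestraint(
            res_a=int(r["residue_a"]), res_b=int(r["residue_b"]),
            lower=lower, upper=upper, k=k,
        )
        for _, r in crosslinks.iterrows()
    ]
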