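"""Minimal structure model: PDB I/O, Cα access, and naive linker-gap filling.

Coordinates are held as flat parallel numpy arrays (one row per atom), which is
all the downstream distance computations need.  Reading and writing goes
through :mod:`gemmi`; residue numbering from the input file is preserved
verbatim (for SurA this is gene numbering including the signal peptide, so the
mature chain spans residues 21-428).

Gap filling is deliberately coarse: missing residues receive a single Cα bead
placed so that consecutive Cα-Cα distances stay near the canonical 3.8 Å
virtual bond.  Rebuilt residues are flagged so results that depend on them can
be reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "Structure",
    "StructureError",
    "read_structure",
    "write_structure",
    "write_ensemble",
    "fill_linker_gaps",
]

CA_VIRTUAL_BOND = 3.8  # Å, consecutive Cα distance in extended protein chains
CA_BOND_TOL = 0.2
MIN_CLASH_DIST = 3.0  # Å, rebuilt beads may not come closer than this to anything


class StructureError(ValueError):
    """Raised for malformed structure input or infeasible geometry."""


@dataclass
class Structure:
    """Atomic coordinates with per-atom annotations.

    Attributes
    ----------
    chain, resnum, resname, atomname, element :
        Parallel arrays, one entry per atom.  ``resnum`` keeps the numbering of
        the source file (gene numbering for SurA).
    xyz :
        ``(n_atoms, 3)`` float array in Å.
    model_id :
        Model number of the selected model (1-based, as in the PDB file).
    rebuilt :
        Boolean flag per atom; True for atoms added by :func:`fill_linker_gaps`.
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    model_id: int = 1
    rebuilt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        for name in ("chain", "resnum", "resname", "atomname", "element"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise StructureError(f"field {name!r} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        self.resnum = self.resnum.astype(int)
        if self.rebuilt is None:
            self.rebuilt = np.zeros(n, dtype=bool)
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError("non-finite coordinates")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def residues(self) -> np.ndarray:
        """Sorted unique residue numbers present in the structure."""
        return np.unique(self.resnum)

    def ca_mask(self) -> np.ndarray:
        return self.atomname == "CA"

    def ca_index(self, resnum: int) -> int:
        idx = np.flatnonzero((self.resnum == resnum) & self.ca_mask())
        if len(idx) == 0:
            raise StructureError(f"residue {resnum} has no CA atom")
        return int(idx[0])

    def ca_coord(self, resnum: int) -> np.ndarray:
        return self.xyz[self.ca_index(resnum)]

    def ca_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (residue numbers, coordinates) for all Cα atoms, residue-sorted."""
        mask = self.ca_mask()
        res = self.resnum[mask]
        order = np.argsort(res, kind="stable")
        return res[order], self.xyz[mask][order]

    def copy(self) -> "Structure":
        return Structure(
            chain=self.chain.copy(),
            resnum=self.resnum.copy(),
            resname=self.resname.copy(),
            atomname=self.atomname.copy(),
            element=self.element.copy(),
            xyz=self.xyz.copy(),
            model_id=self.model_id,
            rebuilt=self.rebuilt.copy(),
        )


def _from_gemmi_model(model: gemmi.Model, model_id: int) -> Structure:
    chain, resnum, resname, atomname, element, xyz = [], [], [], [], [], []
    for ch in model:
        for res in ch:
            if res.het_flag == "H" or res.name == "HOH":
                continue
            for atom in res:
                chain.append(ch.name)
                resnum.append(res.seqid.num)
                resname.append(res.name)
                atomname.append(atom.name)
                element.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise StructureError(f"model {model_id} contains no ATOM records")
    return Structure(
        chain=np.array(chain),
        resnum=np.array(resnum),
        resname=np.array(resname),
        atomname=np.array(atomname),
        element=np.array(element),
        xyz=np.array(xyz),
        model_id=model_id,
    )


def read_structure(text: str, model: int | str = "first") -> Structure:
    """Parse PDB-format ``text`` and return the selected model.

    HETATM records and waters are dropped.  ``model`` may be a 1-based model
    number or ``"first"``.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no models in PDB input")
    if model == "first":
        gm = st[0]
        model_id = gm.num
    else:
        model_id = int(model)
        matches = [m for m in st if m.num == model_id]
        if not matches:
            raise StructureError(f"model {model_id} not found (available: {[m.num for m in st]})")
        gm = matches[0]
    return _from_gemmi_model(gm, model_id)


def _to_gemmi_model(structure: Structure, num: int) -> gemmi.Model:
    model = gemmi.Model(num)
    chain_map: dict[str, gemmi.Chain] = {}
    prev_key = None
    res_obj = None
    for i in range(structure.n_atoms):
        cname = str(structure.chain[i])
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
            model.add_chain(chain_map[cname])
            chain_map[cname] = model[cname]
        key = (cname, int(structure.resnum[i]))
        if key != prev_key:
            res = gemmi.Residue()
            res.name = str(structure.resname[i])
            res.seqid = gemmi.SeqId(int(structure.resnum[i]), " ")
            chain_map[cname].add_residue(res)
            res_obj = chain_map[cname][-1]
            prev_key = key
        atom = gemmi.Atom()
        atom.name = str(structure.atomname[i])
        el = str(structure.element[i]) or "C"
        atom.element = gemmi.Element(el)
        x, y, z = structure.xyz[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res_obj.add_atom(atom)
    return model


def write_structure(structure: Structure) -> str:
    """Serialize a single-model structure to PDB text (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.add_model(_to_gemmi_model(structure, structure.model_id))
    st.setup_entities()
    return st.make_pdb_string()


def write_ensemble(structures: list[Structure]) -> str:
    """Serialize an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    if not structures:
        raise StructureError("empty ensemble")
    st = gemmi.Structure()
    for k, s in enumerate(structures, start=1):
        st.add_model(_to_gemmi_model(s, k))
    st.setup_entities()
    return st.make_pdb_string()


# -- gap filling ----------------------------------------------------------


def _relax_fill(
    a: np.ndarray,
    b: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_iter: int = 400,
    obstacles: np.ndarray | None = None,
    clearance: float = 3.4,
) -> np.ndarray:
    """Place ``k`` beads between fixed anchors ``a`` and ``b`` with ~3.8 Å steps.

    Starts from linear interpolation plus seeded perpendicular noise, then runs
    a position-based relaxation that projects every consecutive distance
    (anchors included) toward 3.8 Å while pushing beads off ``obstacles`` and
    off each other.  Deterministic given the generator state.
    """
    t = np.linspace(0.0, 1.0, k + 2)[1:-1, None]
    beads = a + t * (b - a)
    span = float(np.linalg.norm(b - a))
    # slack between contour length available and straight-line span drives how
    # much the chain has to buckle sideways
    slack = max((k + 1) * CA_VIRTUAL_BOND - span, 0.0)
    beads = beads + rng.standard_normal((k, 3)) * (0.3 + 0.3 * slack / (k + 1))
    chain = np.vstack([a, beads, b])
    for it in range(n_iter):
        vec = np.diff(chain, axis=0)
        dist = np.linalg.norm(vec, axis=1)
        dist[dist < 1e-12] = 1e-12
        corr = (dist - CA_VIRTUAL_BOND) / dist  # fractional excess per segment
        shift = vec * corr[:, None]
        # each free bead absorbs half the length correction of its two
        # adjacent segments; anchors stay fixed
        upd = np.zeros_like(chain)
        upd[1:] -= 0.5 * shift
        upd[:-1] += 0.5 * shift
        if obstacles is not None and len(obstacles):
            d = cdist(chain[1:-1], obstacles)
            j = np.argmin(d, axis=1)
            dmin = d[np.arange(k), j]
            close = dmin < clearance
            if close.any():
                away = chain[1:-1][close] - obstacles[j[close]]
                away /= np.maximum(np.linalg.norm(away, axis=1, keepdims=True), 1e-9)
                upd[1:-1][close] += 0.5 * (clearance - dmin[close])[:, None] * away
        if k > 2:  # self-avoidance of non-adjacent beads
            dm = squareform(pdist(chain[1:-1]))
            np.fill_diagonal(dm, 99.0)
            for off in (1,):
                idx = np.arange(k - off)
                dm[idx, idx + off] = 99.0
                dm[idx + off, idx] = 99.0
            ii, jj = np.where(dm < 3.2)
            for i_, j_ in zip(ii, jj):
                if i_ < j_:
                    v = chain[1 + i_] - chain[1 + j_]
                    nv = np.linalg.norm(v)
                    if nv > 1e-9:
                        push = 0.25 * (3.2 - nv) * v / nv
                        upd[1 + i_] += push
                        upd[1 + j_] -= push
        upd[0] = 0.0
        upd[-1] = 0.0
        chain[1:-1] += upd[1:-1]
        if it > 20 and np.all(
            np.abs(np.linalg.norm(np.diff(chain, axis=0), axis=1) - CA_VIRTUAL_BOND) < 0.05
        ):
            if (
                obstacles is None
                or len(obstacles) == 0
                or cdist(chain[1:-1], obstacles).min() >= clearance - 0.4
            ):
                break
    return chain[1:-1]


def fill_linker_gaps(
    structure: Structure,
    sequence: dict[int, str] | None = None,
    seed: int = 0,
    max_tries: int = 36,
) -> Structure:
    """Fill missing residues in the Cα chain by geometric interpolation.

    Missing residue numbers are those absent between the first and last
    modelled residue.  Each gets a single Cα bead; segments keep consecutive
    Cα-Cα distances within 3.8 ± 0.2 Å and at least 3.0 Å clearance from
    existing atoms (perpendicular zig-zag directions are retried from a seeded
    random sequence until clearance holds).  Deterministic for a given seed.

    Parameters
    ----------
    sequence :
        Optional map residue number -> 3-letter residue name for rebuilt
        residues (defaults to ``GLY``).
    """
    res = structure.residues()
    lo, hi = int(res.min()), int(res.max())
    missing = sorted(set(range(lo, hi + 1)) - set(res.tolist()))
    if not missing:
        return structure
    rng = np.random.default_rng(seed)

    # group into contiguous gaps
    gaps: list[list[int]] = [[missing[0]]]
    for r in missing[1:]:
        if r == gaps[-1][-1] + 1:
            gaps[-1].append(r)
        else:
            gaps.append([r])

    new_rows: list[tuple[int, str, np.ndarray]] = []
    existing_xyz = structure.xyz
    for gap in gaps:
        k = len(gap)
        a_res, b_res = gap[0] - 1, gap[-1] + 1
        try:
            a = structure.ca_coord(a_res)
            b = structure.ca_coord(b_res)
        except StructureError as exc:
            raise StructureError(f"gap {gap[0]}-{gap[-1]} lacks a modelled anchor with CA") from exc
        dist = float(np.linalg.norm(b - a))
        if dist > (k + 1) * (CA_VIRTUAL_BOND + CA_BOND_TOL):
            raise StructureError(
                f"gap {gap[0]}-{gap[-1]}: anchors {dist:.1f} Å apart cannot be bridged "
                f"by {k} residues at ≤ {CA_VIRTUAL_BOND + CA_BOND_TOL} Å per step"
            )
        placed = None
        best = None
        best_clearance = -np.inf
        for _ in range(max_tries):
            beads = _relax_fill(a, b, k, rng, obstacles=existing_xyz, clearance=MIN_CLASH_DIST + 0.4)
            steps = np.linalg.norm(np.diff(np.vstack([a, beads, b]), axis=0), axis=1)
            if np.any(np.abs(steps - CA_VIRTUAL_BOND) > CA_BOND_TOL):
                continue
            clearance = cdist(beads, existing_xyz).min()
            if clearance >= MIN_CLASH_DIST:
                placed = beads
                break
            if clearance > best_clearance:
                best_clearance, best = clearance, beads
        if placed is None:
            if best is None:
                raise StructureError(f"gap {gap[0]}-{gap[-1]}: relaxation failed to reach 3.8 ± 0.2 Å steps")
            placed = best  # least-clashing geometry-valid fallback
        for r, p in zip(gap, placed):
            name = (sequence or {}).get(r, "GLY")
            new_rows.append((r, name, p))

    chain0 = structure.chain[0]
    out = Structure(
        chain=np.concatenate([structure.chain, np.full(len(new_rows), chain0)]),
        resnum=np.concatenate([structure.resnum, np.array([r for r, _, _ in new_rows])]),
        resname=np.concatenate([structure.resname, np.array([n for _, n, _ in new_rows])]),
        atomname=np.concatenate([structure.atomname, np.full(len(new_rows), "CA")]),
        element=np.concatenate([structure.element, np.full(len(new_rows), "C")]),
        xyz=np.vstack([structure.xyz, np.array([p for _, _, p in new_rows])]),
        model_id=structure.model_id,
        rebuilt=np.concatenate([structure.rebuilt, np.ones(len(new_rows), dtype=bool)]),
    )
    order = np.argsort(out.resnum, kind="stable")
    return Structure(
        chain=out.chain[order],
        resnum=out.resnum[order],
        resname=out.resname[order],
        atomname=out.atomname[order],
        element=out.element[order],
        xyz=out.xyz[order],
        model_id=out.model_id,
        rebuilt=out.rebuilt[order],
    )
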