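"""Deterministic toy protein-ligand-water complexes with planted geometry.

Real benchmark structures cannot be bundled, so every other module is
exercised on synthetic pockets built here. The generator trades chemical
realism for exact geometric control:

* the *ligand* is a small rigid arrangement of carbons (rod, hexagonal
  ring, or blob) with selected atoms turned into oxygens where a
  hydrogen-bond anchor is needed;
* the *pseudo-protein* is a space-filling matrix of carbon markers (one
  GLY-like residue each) on a cubic lattice surrounding the ligand, so
  that all space in the search box is occupied except where we carve it;
* each *planted bridging site* is a spherical cavity carved into the
  matrix at a lattice point near the ligand, given one polar ligand
  anchor and one serine-like protein hydroxyl at hydrogen-bond range, and
  marked by a crystallographic water at its center;
* *decoy waters* sit in the 3-5 Å band from the ligand: local but never
  bridging.

Because sites are lattice-aligned and cavities are tight, running the
placement pipeline with the parameters the fixture was built against
yields exactly one predicted water per planted site, well inside the
1.4 Å recapture criterion — the module's defining guarantee, enforced
constructively: every emitted fixture is validated, with a bounded
jitter-and-retry loop, before it is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FixtureInfeasibleError
from .evaluation import EvalParams, find_native_waters
from .placement import PlacementParams, build_grid, place_waters
from .structio import Atom, InterfaceComplex, coords, load_complex, write_waters

__all__ = [
    "FixtureSpec",
    "PlantedSite",
    "Fixture",
    "generate_complex",
    "generate_calibration_complex",
    "generate_benchmark",
]

_LIGAND_RESNAME = "LIG"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex.

    ``site_ligand_window`` bounds the planted-site-to-nearest-ligand-atom
    distance (must sit between the clash radius and the H-bond shell);
    ``min_site_separation`` keeps cavities far enough apart that their
    void points can never single-link across (two cavities of surviving
    radius sqrt(2) plus a 2 Å linkage step require > 4.83 Å).
    ``d_protein`` is the planted site-to-protein-hydroxyl distance.
    """

    seed: int = 0
    ligand_shape: str = "rod"  # rod | ring | blob
    n_planted_sites: int = 1
    n_decoy_waters: int = 0
    d_protein: float = 2.45
    site_ligand_window: tuple[float, float] = (2.05, 2.60)
    min_site_separation: float = 4.85
    cavity_radius: float = 3.2
    matrix_spacing: float = 1.0
    pocket_padding: float = 2.6
    max_retries: int = 30

    def __post_init__(self) -> None:
        if self.ligand_shape not in ("rod", "ring", "blob"):
            raise ValueError(f"unknown ligand_shape {self.ligand_shape!r}")
        if not 0 <= self.n_planted_sites <= 6:
            raise ValueError("n_planted_sites must be in [0, 6]")
        if self.ligand_shape != "rod" and self.n_planted_sites > 2:
            raise ValueError("ring/blob ligands support at most 2 planted sites")


@dataclass
class PlantedSite:
    """Ground-truth bridging site: coordinate plus realized contact distances."""

    coord: np.ndarray
    d_ligand: float
    d_protein: float


@dataclass
class Fixture:
    spec: FixtureSpec
    complex: InterfaceComplex
    planted_sites: list[PlantedSite]
    pdb_text: str
    source_id: str


def _rod_ligand(n_sites: int) -> np.ndarray:
    n = 5 if n_sites <= 2 else (9 if n_sites <= 4 else 11)
    x = (np.arange(n) - (n - 1) / 2.0) * 1.5
    return np.column_stack([x, np.zeros(n), np.zeros(n)])


def _ring_ligand() -> np.ndarray:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.round(np.column_stack(
        [1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)]), 3)


def _blob_ligand(rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    while len(pts) < 7:
        p = rng.uniform(-1.8, 1.8, size=3)
        if np.linalg.norm(p) <= 1.8 and all(
                np.linalg.norm(p - q) >= 1.2 for q in pts):
            pts.append(p)
    arr = np.array(pts)
    return np.round(arr - arr.mean(axis=0), 3)


def _ligand_coords(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.ligand_shape == "rod":
        return _rod_ligand(spec.n_planted_sites)
    if spec.ligand_shape == "ring":
        return _ring_ligand()
    return _blob_ligand(rng)


def _pick_sites(lattice: np.ndarray, lig_xyz: np.ndarray, spec: FixtureSpec,
                rng: np.random.Generator) -> list[np.ndarray] | None:
    from scipy.spatial.distance import cdist

    d = cdist(lattice, lig_xyz).min(axis=1)
    lo, hi = spec.site_ligand_window
    candidates = lattice[(d > lo) & (d < hi)]
    if len(candidates) < spec.n_planted_sites:
        return None
    order = rng.permutation(len(candidates))
    chosen: list[np.ndarray] = []
    for idx in order:
        p = candidates[idx]
        if all(np.linalg.norm(p - q) >= spec.min_site_separation for q in chosen):
            chosen.append(p)
        if len(chosen) == spec.n_planted_sites:
            return chosen
    return None


def _protein_slot(index: int) -> tuple[int, str]:
    """(residue number, chain) for the i-th pseudo-protein residue.

    PDB residue numbers are 4 columns wide, so the matrix rolls over to
    a fresh chain every 9999 residues.
    """
    return index % 9999 + 1, "ABCDEFGHIJ"[index // 9999]


def _build_attempt(spec: FixtureSpec, attempt: int,
                   params: PlacementParams) -> tuple[list[Atom], list[PlantedSite]]:
    rng = np.random.default_rng([spec.seed, attempt])
    lig_xyz = np.round(_ligand_coords(spec, rng), 3)
    center = lig_xyz.mean(axis=0)
    grid = build_grid(lig_xyz, params.grid_spacing, params.min_edge)

    sites = ([] if spec.n_planted_sites == 0
             else _pick_sites(grid.points, lig_xyz, spec, rng))
    if sites is None:
        raise FixtureInfeasibleError(
            f"could not place {spec.n_planted_sites} sites "
            f"{spec.min_site_separation} A apart in the search box")

    lig_elements = ["C"] * len(lig_xyz)
    planted: list[PlantedSite] = []
    protein_polar: list[np.ndarray] = []
    for site in sites:
        dists = np.linalg.norm(lig_xyz - site, axis=1)
        anchor = int(np.argmin(dists))
        lig_elements[anchor] = "O"
        w = site - center
        w = w / np.linalg.norm(w)
        pp = np.round(site + spec.d_protein * w, 3)
        protein_polar.append(pp)
        planted.append(PlantedSite(coord=np.round(site, 3),
                                   d_ligand=float(dists[anchor]),
                                   d_protein=spec.d_protein))

    # decoy waters: local (3-5 A from the ligand) but never bridging
    decoys: list[np.ndarray] = []
    guard = [s.coord for s in planted] + protein_polar
    for _ in range(spec.n_decoy_waters):
        for _try in range(200):
            anchor_xyz = lig_xyz[rng.integers(len(lig_xyz))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = np.round(anchor_xyz + rng.uniform(3.4, 4.6) * u, 3)
            d_lig = np.linalg.norm(lig_xyz - pos, axis=1).min()
            if not 3.25 < d_lig < 4.75:
                continue
            if any(np.linalg.norm(pos - g) < 2.0 for g in guard + decoys):
                continue
            decoys.append(pos)
            break
        else:
            raise FixtureInfeasibleError("could not place a decoy water")

    # space-filling matrix: cubic lattice aligned with the search grid,
    # carved out around each planted site
    radius = grid.edge / 2.0 * math.sqrt(3) + spec.pocket_padding
    n = int(math.ceil(radius / spec.matrix_spacing))
    ax = np.arange(-n, n + 1) * spec.matrix_spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    matrix = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center
    keep = np.linalg.norm(matrix - center, axis=1) <= radius
    for site in planted:
        keep &= np.linalg.norm(matrix - site.coord, axis=1) >= spec.cavity_radius
    for xyz in list(lig_xyz) + decoys:
        keep &= np.linalg.norm(matrix - xyz, axis=1) >= 0.8
    matrix = np.round(matrix[keep], 3)

    atoms: list[Atom] = []
    serial = 0
    for xyz in matrix:
        serial += 1
        atoms.append(Atom(serial, "CA", "C", xyz, "GLY",
                          *_protein_slot(serial - 1), role="protein"))
    for xyz in protein_polar:
        serial += 1
        atoms.append(Atom(serial, "OG", "O", xyz, "SER",
                          *_protein_slot(serial - 1), role="protein"))
    n_c = n_o = 0
    for xyz, elem in zip(lig_xyz, lig_elements):
        serial += 1
        if elem == "O":
            n_o += 1
            name = f"O{n_o}"
        else:
            n_c += 1
            name = f"C{n_c}"
        atoms.append(Atom(serial, name, elem, xyz, _LIGAND_RESNAME, 1, "X", "ligand"))
    for i, xyz in enumerate([s.coord for s in planted] + decoys, start=1):
        serial += 1
        atoms.append(Atom(serial, "O", "O", xyz, "HOH", i, "S", "water"))
    return atoms, planted


def _assemble(atoms: list[Atom], source_id: str) -> tuple[InterfaceComplex, str]:
    cx = InterfaceComplex(
        protein_atoms=[a for a in atoms if a.role == "protein"],
        ligand_atoms=[a for a in atoms if a.role == "ligand"],
        water_oxygens=[a for a in atoms if a.role == "water"],
        other_atoms=[a for a in atoms if a.role == "other"],
        source_id=source_id,
    )
    pdb_text = write_waters(cx, [])
    loaded = load_complex(pdb_text, _LIGAND_RESNAME, source_id=source_id)
    return loaded, pdb_text


def _validate(loaded: InterfaceComplex, planted: list[PlantedSite],
              n_decoys: int, params: PlacementParams,
              eval_params: EvalParams) -> str | None:
    bridging, local = find_native_waters(loaded, eval_params)
    if len(bridging) != len(planted):
        return f"expected {len(planted)} bridging waters, found {len(bridging)}"
    if len(local) != len(planted) + n_decoys:
        return f"expected {len(planted) + n_decoys} local waters, found {len(local)}"
    heavy = coords(loaded.protein_atoms + loaded.ligand_atoms)
    placed = place_waters(loaded, params)
    pxyz = (np.array([p.coord for p in placed])
            if placed else np.empty((0, 3)))
    for site in planted:
        if np.linalg.norm(heavy - site.coord, axis=1).min() < params.clash_dist:
            return "planted site violates the clash radius"
        if len(pxyz) == 0:
            return "no waters placed"
        hits = np.linalg.norm(pxyz - site.coord, axis=1) <= eval_params.success_cutoff
        if hits.sum() != 1:
            return f"site not uniquely recaptured ({int(hits.sum())} hits)"
    return None


def generate_complex(
    spec: FixtureSpec,
    params: PlacementParams = PlacementParams(),
    eval_params: EvalParams = EvalParams(),
    *,
    source_id: str = "",
) -> Fixture:
    """Build one validated fixture; deterministic per spec.

    Retries with jittered internal choices up to ``spec.max_retries``
    when a random arrangement fails validation, then raises
    :class:`FixtureInfeasibleError` naming the violated constraint.
    """
    source_id = source_id or f"SYN-{spec.seed}"
    last_reason = "no attempt succeeded"
    for attempt in range(spec.max_retries):
        try:
            atoms, planted = _build_attempt(spec, attempt, params)
        except FixtureInfeasibleError as exc:
            last_reason = str(exc)
            continue
        loaded, pdb_text = _assemble(atoms, source_id)
        reason = _validate(loaded, planted, spec.n_decoy_waters, params, eval_params)
        if reason is None:
            return Fixture(spec=spec, complex=loaded, planted_sites=planted,
                           pdb_text=pdb_text, source_id=source_id)
        last_reason = reason
    raise FixtureInfeasibleError(
        f"fixture infeasible after {spec.max_retries} attempts: {last_reason}")


# --- calibration family for parameter recovery -------------------------------

#: relative geometry of the calibration pocket (see generate_calibration_complex)
_CAL_SITE = np.array([0.0, 2.0, 1.0])
_CAL_CAP_SITE = np.array([0.0, 4.1, 1.0])        # 2.1 A from the site
_CAL_CAP_NEIGHBORS = [np.array([2.7, 2.0, 1.0]),   # 1.7 A from each +-x, +z
                      np.array([-2.7, 2.0, 1.0]),
                      np.array([0.0, 2.0, 3.7]),
                      np.array([0.0, 2.0, -1.9])]  # 1.9 A from the -z neighbor
_CAL_PROTEIN_POLAR = np.array([2.45, 2.0, 1.0])

_SIGNED_PERMS = [(perm, signs)
                 for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2),
                              (1, 2, 0), (2, 0, 1), (2, 1, 0))
                 for signs in ((1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
                               (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1))]


def generate_calibration_complex(seed: int = 0) -> Fixture:
    """One-site pocket whose placement succeeds only near clash_dist = 2.0.

    The cavity is over-carved (radius 3.2) and then re-lined with
    calibration carbons: one exactly 2.1 Å from the site (so the site's
    grid point is pruned once clash_dist exceeds 2.1) and others 1.7 or
    1.9 Å from the site's open lattice neighbors (so those neighbors
    join the void — and drag the centroid off the site — once clash_dist
    drops to 1.9). The per-native nearest-water objective is therefore 0
    only for clash_dist in the (1.9, 2.1] window, a penalty above it (no
    water placed) and strictly positive below it (drifted centroid). The seed picks a lattice-preserving rigid motion
    (signed axis permutation + integer translation), giving a family of
    equivalent pockets.
    """
    rng = np.random.default_rng(seed)
    perm, signs = _SIGNED_PERMS[rng.integers(len(_SIGNED_PERMS))]
    shift = rng.integers(-20, 21, size=3).astype(float)

    def tf(xyz: np.ndarray) -> np.ndarray:
        return np.array([signs[k] * xyz[perm[k]] for k in range(3)]) + shift

    lig_xyz = _rod_ligand(1)               # 5 carbons along x, centered
    anchor = 2                             # the central atom becomes the O anchor
    site = tf(_CAL_SITE)

    spec = FixtureSpec(seed=seed, n_planted_sites=1)
    radius = 3.0 * math.sqrt(3) + spec.pocket_padding
    n = int(math.ceil(radius))
    ax = np.arange(-n, n + 1, dtype=float)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    matrix = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + shift
    keep = np.linalg.norm(matrix - shift, axis=1) <= radius
    keep &= np.linalg.norm(matrix - site, axis=1) >= spec.cavity_radius
    lig_world = np.array([tf(x) for x in lig_xyz])
    for xyz in lig_world:
        keep &= np.linalg.norm(matrix - xyz, axis=1) >= 0.8
    matrix = matrix[keep]

    atoms: list[Atom] = []
    serial = 0
    for xyz in matrix:
        serial += 1
        atoms.append(Atom(serial, "CA", "C", xyz, "GLY",
                          *_protein_slot(serial - 1), role="protein"))
    for rel in [_CAL_CAP_SITE] + _CAL_CAP_NEIGHBORS:
        serial += 1
        atoms.append(Atom(serial, "CA", "C", tf(rel), "GLY",
                          *_protein_slot(serial - 1), role="protein"))
    serial += 1
    atoms.append(Atom(serial, "OG", "O", tf(_CAL_PROTEIN_POLAR), "SER",
                      *_protein_slot(serial - 1), role="protein"))
    for i, xyz in enumerate(lig_world):
        serial += 1
        elem = "O" if i == anchor else "C"
        name = "O1" if i == anchor else f"C{i + 1}"
        atoms.append(Atom(serial, name, elem, xyz, _LIGAND_RESNAME, 1, "X", "ligand"))
    serial += 1
    atoms.append(Atom(serial, "O", "O", site, "HOH", 1, "S", "water"))

    source_id = f"CAL-{seed}"
    loaded, pdb_text = _assemble(atoms, source_id)
    planted = [PlantedSite(coord=site,
                           d_ligand=float(np.linalg.norm(site - tf(lig_xyz[anchor]))),
                           d_protein=float(np.linalg.norm(site - tf(_CAL_PROTEIN_POLAR))))]
    return Fixture(spec=spec, complex=loaded, planted_sites=planted,
                   pdb_text=pdb_text, source_id=source_id)


def generate_benchmark(
    n_complexes: int,
    seed: int,
    out_dir: str | Path | None = None,
    params: PlacementParams = PlacementParams(),
    eval_params: EvalParams = EvalParams(),
) -> tuple[list[Fixture], pd.DataFrame]:
    """A desk-scale benchmark: fixtures with 0-6 bridging waters each.

    Returns the fixtures and a manifest (id, ligand, n_bridging, n_local,
    resolution stub, filename); when ``out_dir`` is given, PDB files and
    ``manifest.tsv`` are written there.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    rng = np.random.default_rng(seed)
    fixtures: list[Fixture] = []
    rows = []
    for i in range(n_complexes):
        n_sites = int(rng.integers(0, 7))
        shape = ("rod" if n_sites > 2
                 else ["rod", "ring", "blob"][rng.integers(3)])
        spec = FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            ligand_shape=shape,
            n_planted_sites=n_sites,
            n_decoy_waters=int(rng.integers(0, 4)),
        )
        source_id = f"SYN{i:03d}"
        fx = generate_complex(spec, params, eval_params, source_id=source_id)
        fixtures.append(fx)
        bridging, local = find_native_waters(fx.complex, eval_params)
        rows.append({
            "id": source_id,
            "ligand": _LIGAND_RESNAME,
            "n_bridging": len(bridging),
            "n_local": len(local),
            "resolution": round(float(rng.uniform(0.9, 2.2)), 2),
            "filename": f"{source_id}.pdb",
        })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fx, row in zip(fixtures, rows):
            (out / row["filename"]).write_text(fx.pdb_text)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return fixtures, manifest
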