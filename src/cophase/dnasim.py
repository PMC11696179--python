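"""Reduced coarse-grained simulation of oligomeric CO-NF-Y complexes binding
a multi-motif promoter fragment in a periodic box.

The model keeps the composition and contact-counting conventions of the
residue-resolution study system (15 DNA double helices carrying four CO
response elements each, 60 CO-NF-Y binding units, a 120-nm cubic box, a
1.2-nm molecular contact cutoff, first trajectory half discarded as
equilibration) while reducing resolution to one bead per CO-NF-Y binding
unit and roughly ten base pairs per DNA bead.  Oligomeric complexes are
linear chains of 1-5 units held by stiff harmonic links.

Energetics (reduced units: lengths in nm, energies in kT, mobility 1):

* harmonic bonds along DNA and within complexes (rest 3.4 nm, the ~10-bp
  bead pitch), with worm-like-chain bending stiffness on DNA (the ~170-bp
  fragment is much shorter than the dsDNA persistence length) and angular
  stiffness along oligomers (structured assemblies, not floppy polymers);
* soft harmonic repulsion between binding units (sigma 2.4 nm, which also
  enforces at-most-one unit in a motif's attractive minimum) and between
  DNA beads (sigma 2.0 nm);
* a short-range attractive well between units and DNA beads,
  ``U(r) = -eps * (1 - (r/rw)**2)**2`` for ``r < rw`` (rw = 2.4 nm), with
  depth ``well_depth`` at the four motif beads and the weaker
  ``nonspecific_depth`` elsewhere on the DNA (generic protein-DNA
  attraction).  Units have no excluded volume against DNA, so the
  zero-affinity limit is an ideal gas with an exact random-contact
  expectation.

Dynamics are overdamped Langevin with periodic wrapping; a Metropolis
Monte-Carlo mode over unit positions provides an equilibrium cross-check.
Bound-count statistics report, per frame and per DNA chain, the number of
binding units within the contact cutoff of that chain (all beads by
default, motif beads only as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import spearmanr

CONTACT_CUTOFF_NM = 1.2
FULL_BOX_NM = 120.0
FULL_UNITS = 60
FULL_DNA_CHAINS = 15
BP_PER_BEAD = 10
RISE_PER_BP_NM = 0.34

DNA_BOND_NM = BP_PER_BEAD * RISE_PER_BP_NM  # 3.4
#: rest length of the harmonic link joining units of an oligomer; matched to
#: the DNA bead pitch so an s-mer can engage s consecutive ~10-bp segments
UNIT_BOND_NM = 3.4
#: angular stiffness along an oligomer (U = k * (1 + cos phi) per triple):
#: oligomers are structured assemblies held by native contacts, not floppy
#: polymers, so the reduced s-mer is a semi-rigid rod
ANGLE_K = 10.0
#: bending stiffness of DNA: the ~170-bp fragment is shorter than the ~50 nm
#: persistence length of dsDNA, so chains behave as near-straight rods
#: (discrete worm-like chain, k ~ lp/b in kT)
DNA_ANGLE_K = 15.0
BOND_K = 100.0          # kT / nm^2
REP_K = 25.0            # kT / nm^2, soft-core
SIGMA_UNIT = 2.4        # nm, unit-unit
SIGMA_DNA = 2.0         # nm, DNA-DNA
WELL_RANGE_NM = 2.4     # nm, attraction capture range


def core_fragment_sequence() -> str:
    """The CORE-containing promoter fragment packaged with the library."""
    text = resources.files("cophase.data").joinpath("ft_core_fragment.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def beads_for_fragment(sequence: str | None = None) -> int:
    """Number of DNA beads for a sequence at ~10 bp per bead."""
    seq = core_fragment_sequence() if sequence is None else sequence
    return max(2, int(round(len(seq) / BP_PER_BEAD)))


@dataclass
class DnaChain:
    bead_positions: np.ndarray  # (L, 3) nm
    motif_bead_indices: np.ndarray  # (4,)


@dataclass
class OligomerComplex:
    unit_indices: np.ndarray
    oligomer_state: int


@dataclass
class ReducedSystem:
    box_length: float
    dna_pos: np.ndarray          # (n_dna, L, 3)
    motif_indices: np.ndarray    # (n_motifs,)
    unit_pos: np.ndarray         # (n_units, 3)
    complexes: list
    bond_pairs: np.ndarray       # (n_bonds, 2) unit-index pairs
    angle_triples: np.ndarray    # (n_angles, 3) consecutive units in a complex
    oligomer_state: int
    n_remainder_monomers: int
    temperature: float = 1.0
    contact_cutoff: float = CONTACT_CUTOFF_NM
    well_depth: float = 5.0      # kT at motif beads
    nonspecific_depth: float = 1.2  # kT at other DNA beads
    seed: int = 0

    @property
    def n_units(self) -> int:
        return self.unit_pos.shape[0]

    @property
    def n_dna(self) -> int:
        return self.dna_pos.shape[0]

    @property
    def dna_chains(self) -> list:
        return [DnaChain(self.dna_pos[i], self.motif_indices) for i in range(self.n_dna)]


@dataclass
class Trajectory:
    times: np.ndarray
    unit_frames: np.ndarray  # (F, n_units, 3)
    dna_frames: np.ndarray   # (F, n_dna, L, 3)
    box_length: float
    motif_indices: np.ndarray
    contact_cutoff: float


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def build_system(
    oligomer_state: int,
    units: int = 16,
    n_dna: int = 4,
    box_nm: float = 36.0,
    dna_beads: int = 9,
    n_motifs: int = 4,
    well_depth: float = 5.0,
    nonspecific_depth: float = 1.2,
    temperature: float = 1.0,
    seed: int = 0,
    max_attempts: int = 2000,
) -> ReducedSystem:
    """Place DNA chains and oligomeric complexes uniformly at random.

    ``units // oligomer_state`` s-mers are built; any remainder enters as
    monomers (recorded on the system).  Chains are straight rods of
    ``dna_beads`` beads with ``n_motifs`` motif beads evenly spaced along
    them; packing retries until nothing overlaps.
    """
    if not 1 <= oligomer_state <= 5:
        raise ValueError("oligomer_state must be in 1..5")
    if units < 1 or n_dna < 1:
        raise ValueError("need at least one unit and one chain")
    rng = np.random.default_rng(seed)

    motif_indices = np.unique(
        np.round(np.linspace(1, dna_beads - 2, n_motifs)).astype(int)
    )
    if motif_indices.size != n_motifs:
        raise ValueError("chain too short to hold the motif sites")

    # DNA rods
    dna_pos = np.empty((n_dna, dna_beads, 3))
    placed_beads: list[np.ndarray] = []
    for c in range(n_dna):
        for attempt in range(max_attempts):
            origin = rng.uniform(0, box_nm, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            beads = origin + np.arange(dna_beads)[:, None] * DNA_BOND_NM * direction
            ok = True
            for other in placed_beads:
                d = _min_image(beads[:, None, :] - other[None, :, :], box_nm)
                if (np.linalg.norm(d, axis=-1) < SIGMA_DNA).any():
                    ok = False
                    break
            if ok:
                dna_pos[c] = beads
                placed_beads.append(beads)
                break
        else:
            raise RuntimeError(f"could not pack DNA chain {c} after {max_attempts} attempts")

    # complexes
    n_full = units // oligomer_state
    remainder = units % oligomer_state
    sizes = [oligomer_state] * n_full + [1] * remainder
    unit_pos = np.empty((units, 3))
    complexes = []
    bond_pairs = []
    angle_triples = []
    placed_units: list[np.ndarray] = []
    idx = 0
    all_dna = dna_pos.reshape(-1, 3)
    for s in sizes:
        for attempt in range(max_attempts):
            origin = rng.uniform(0, box_nm, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            beads = origin + np.arange(s)[:, None] * UNIT_BOND_NM * direction
            ok = True
            for other in placed_units:
                d = _min_image(beads[:, None, :] - other[None, :, :], box_nm)
                if (np.linalg.norm(d, axis=-1) < SIGMA_UNIT).any():
                    ok = False
                    break
            if ok:
                # start outside the attraction range of any DNA bead
                d = _min_image(beads[:, None, :] - all_dna[None, :, :], box_nm)
                ok = (np.linalg.norm(d, axis=-1) > WELL_RANGE_NM).all()
            if ok:
                ids = np.arange(idx, idx + s)
                unit_pos[ids] = beads
                complexes.append(OligomerComplex(ids, s))
                bond_pairs.extend([(int(ids[i]), int(ids[i + 1])) for i in range(s - 1)])
                angle_triples.extend(
                    [(int(ids[i]), int(ids[i + 1]), int(ids[i + 2])) for i in range(s - 2)]
                )
                placed_units.append(beads)
                idx += s
                break
        else:
            raise RuntimeError(f"could not pack complex after {max_attempts} attempts")

    return ReducedSystem(
        box_length=float(box_nm),
        dna_pos=dna_pos % box_nm,
        motif_indices=motif_indices,
        unit_pos=unit_pos % box_nm,
        complexes=complexes,
        bond_pairs=np.array(bond_pairs, dtype=int).reshape(-1, 2),
        angle_triples=np.array(angle_triples, dtype=int).reshape(-1, 3),
        oligomer_state=oligomer_state,
        n_remainder_monomers=remainder,
        temperature=temperature,
        well_depth=well_depth,
        nonspecific_depth=nonspecific_depth,
        seed=seed,
    )


def full_scale(oligomer_state: int, seed: int = 0, **kwargs) -> ReducedSystem:
    """The full study composition: 60 units, 15 chains, 120-nm box, and a
    chain length set by the packaged CORE fragment (~10 bp per bead)."""
    kwargs.setdefault("units", FULL_UNITS)
    kwargs.setdefault("n_dna", FULL_DNA_CHAINS)
    kwargs.setdefault("box_nm", FULL_BOX_NM)
    kwargs.setdefault("dna_beads", beads_for_fragment())
    return build_system(oligomer_state, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# forces and energies


def _bead_depths(system: ReducedSystem) -> np.ndarray:
    """Attraction depth per DNA bead (flattened): motif vs nonspecific."""
    depths = np.full(system.dna_pos.shape[1], system.nonspecific_depth)
    depths[system.motif_indices] = system.well_depth
    return np.tile(depths, system.n_dna)


def _forces(unit_pos, dna_flat, system, depths, dna_bond_slices):
    box = system.box_length
    n_units = unit_pos.shape[0]
    f_units = np.zeros_like(unit_pos)
    f_dna = np.zeros_like(dna_flat)

    # unit <- DNA attraction (and reaction on DNA)
    d = _min_image(unit_pos[:, None, :] - dna_flat[None, :, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    rw2 = WELL_RANGE_NM**2
    in_well = r2 < rw2
    if in_well.any():
        # F = -dU/dr * r_hat = -(4 eps r / rw^2)(1 - r^2/rw^2) r_hat
        coef = np.where(in_well, -4.0 * depths[None, :] / rw2 * (1.0 - r2 / rw2), 0.0)
        fv = coef[:, :, None] * d
        f_units += fv.sum(axis=1)
        f_dna -= fv.sum(axis=0)

    # unit-unit soft repulsion (bonded pairs excluded)
    if n_units > 1:
        du = _min_image(unit_pos[:, None, :] - unit_pos[None, :, :], box)
        ru = np.sqrt(np.einsum("ijk,ijk->ij", du, du))
        np.fill_diagonal(ru, np.inf)
        if system.bond_pairs.size:
            ru[system.bond_pairs[:, 0], system.bond_pairs[:, 1]] = np.inf
            ru[system.bond_pairs[:, 1], system.bond_pairs[:, 0]] = np.inf
        overlap = ru < SIGMA_UNIT
        if overlap.any():
            ru_safe = np.where(overlap, ru, 1.0)
            mag = np.where(overlap, REP_K * (SIGMA_UNIT - ru_safe) / ru_safe, 0.0)
            f_units += (mag[:, :, None] * du).sum(axis=1)

    # complex bonds
    if system.bond_pairs.size:
        i, j = system.bond_pairs[:, 0], system.bond_pairs[:, 1]
        db = _min_image(unit_pos[i] - unit_pos[j], box)
        rb = np.linalg.norm(db, axis=1)
        fb = (-BOND_K * (rb - UNIT_BOND_NM) / rb)[:, None] * db
        np.add.at(f_units, i, fb)
        np.add.at(f_units, j, -fb)

    # complex angle stiffness, U = ANGLE_K * (1 + cos phi) per triple
    if system.angle_triples.size:
        a, b, c = (system.angle_triples[:, k] for k in range(3))
        u = _min_image(unit_pos[a] - unit_pos[b], box)
        v = _min_image(unit_pos[c] - unit_pos[b], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosphi = np.einsum("ij,ij->i", u, v) / (nu * nv)
        fa = -ANGLE_K * (v / (nu * nv)[:, None] - (cosphi / nu**2)[:, None] * u)
        fc = -ANGLE_K * (u / (nu * nv)[:, None] - (cosphi / nv**2)[:, None] * v)
        np.add.at(f_units, a, fa)
        np.add.at(f_units, c, fc)
        np.add.at(f_units, b, -(fa + fc))

    # DNA bonds (consecutive beads within each chain)
    i, j = dna_bond_slices
    db = _min_image(dna_flat[i] - dna_flat[j], box)
    rb = np.linalg.norm(db, axis=1)
    fb = (-BOND_K * (rb - DNA_BOND_NM) / rb)[:, None] * db
    np.add.at(f_dna, i, fb)
    np.add.at(f_dna, j, -fb)

    # DNA bending stiffness (worm-like chain, U = k * (1 + cos phi))
    n_dna_beads = dna_flat.shape[0]
    L = n_dna_beads // system.n_dna
    if L >= 3:
        base = np.arange(system.n_dna)[:, None] * L + np.arange(L - 2)[None, :]
        a = base.ravel()
        b = a + 1
        c = a + 2
        u = _min_image(dna_flat[a] - dna_flat[b], box)
        v = _min_image(dna_flat[c] - dna_flat[b], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosphi = np.einsum("ij,ij->i", u, v) / (nu * nv)
        fa = -DNA_ANGLE_K * (v / (nu * nv)[:, None] - (cosphi / nu**2)[:, None] * u)
        fc = -DNA_ANGLE_K * (u / (nu * nv)[:, None] - (cosphi / nv**2)[:, None] * v)
        np.add.at(f_dna, a, fa)
        np.add.at(f_dna, c, fc)
        np.add.at(f_dna, b, -(fa + fc))

    # DNA-DNA soft repulsion (adjacent beads sit beyond sigma; no exclusion needed)
    dd = _min_image(dna_flat[:, None, :] - dna_flat[None, :, :], box)
    rd = np.sqrt(np.einsum("ijk,ijk->ij", dd, dd))
    np.fill_diagonal(rd, np.inf)
    overlap = rd < SIGMA_DNA
    if overlap.any():
        rd_safe = np.where(overlap, rd, 1.0)
        mag = np.where(overlap, REP_K * (SIGMA_DNA - rd_safe) / rd_safe, 0.0)
        f_dna += (mag[:, :, None] * dd).sum(axis=1)

    return f_units, f_dna


def unit_energy(unit_pos: np.ndarray, system: ReducedSystem) -> float:
    """Total energy of the binding units against frozen DNA (for MC moves)."""
    box = system.box_length
    dna_flat = system.dna_pos.reshape(-1, 3)
    depths = _bead_depths(system)
    d = _min_image(unit_pos[:, None, :] - dna_flat[None, :, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    rw2 = WELL_RANGE_NM**2
    e = float(np.sum(np.where(r2 < rw2, -depths[None, :] * (1 - r2 / rw2) ** 2, 0.0)))
    if unit_pos.shape[0] > 1:
        du = _min_image(unit_pos[:, None, :] - unit_pos[None, :, :], box)
        ru = np.sqrt(np.einsum("ijk,ijk->ij", du, du))
        iu = np.triu_indices(unit_pos.shape[0], 1)
        r_ut = ru[iu]
        mask = np.ones(r_ut.size, dtype=bool)
        if system.bond_pairs.size:
            flat = iu[0] * unit_pos.shape[0] + iu[1]
            bonded = set(
                int(min(a, b)) * unit_pos.shape[0] + int(max(a, b))
                for a, b in system.bond_pairs
            )
            mask = np.array([f not in bonded for f in flat])
        e += float(np.sum(np.where(r_ut[mask] < SIGMA_UNIT, 0.5 * REP_K * (SIGMA_UNIT - r_ut[mask]) ** 2, 0.0)))
    if system.bond_pairs.size:
        i, j = system.bond_pairs[:, 0], system.bond_pairs[:, 1]
        rb = np.linalg.norm(_min_image(unit_pos[i] - unit_pos[j], box), axis=1)
        e += float(np.sum(0.5 * BOND_K * (rb - UNIT_BOND_NM) ** 2))
    if system.angle_triples.size:
        a, b, c = (system.angle_triples[:, k] for k in range(3))
        u = _min_image(unit_pos[a] - unit_pos[b], box)
        v = _min_image(unit_pos[c] - unit_pos[b], box)
        cosphi = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        e += float(np.sum(ANGLE_K * (1.0 + cosphi)))
    return e


@njit(cache=False)
def _chunk_steps(
    unit_pos, dna_flat, bond_i, bond_j, ang_a, ang_b, ang_c,
    dna_i, dna_j, dang_a, dang_b, dang_c, depths,
    box, dt, mob, noise_u, noise_d,
):
    """Advance one sampling interval of overdamped Langevin steps in place.

    Explicit pair loops with squared-distance early exits; numerically the
    same model as :func:`_forces` (which serves as the reference
    implementation in tests).
    """
    n_steps = noise_u.shape[0]
    nu = unit_pos.shape[0]
    nd = dna_flat.shape[0]
    rw2 = WELL_RANGE_NM * WELL_RANGE_NM
    f_u = np.empty((nu, 3))
    f_d = np.empty((nd, 3))
    for step in range(n_steps):
        f_u[:] = 0.0
        f_d[:] = 0.0
        # unit <-> DNA attraction
        for i in range(nu):
            for j in range(nd):
                dx = unit_pos[i, 0] - dna_flat[j, 0]
                dy = unit_pos[i, 1] - dna_flat[j, 1]
                dz = unit_pos[i, 2] - dna_flat[j, 2]
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rw2:
                    coef = -4.0 * depths[j] / rw2 * (1.0 - r2 / rw2)
                    f_u[i, 0] += coef * dx
                    f_u[i, 1] += coef * dy
                    f_u[i, 2] += coef * dz
                    f_d[j, 0] -= coef * dx
                    f_d[j, 1] -= coef * dy
                    f_d[j, 2] -= coef * dz
        # unit-unit soft repulsion (bonded pairs corrected afterwards)
        for i in range(nu):
            for j in range(i + 1, nu):
                dx = unit_pos[i, 0] - unit_pos[j, 0]
                dy = unit_pos[i, 1] - unit_pos[j, 1]
                dz = unit_pos[i, 2] - unit_pos[j, 2]
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < SIGMA_UNIT * SIGMA_UNIT:
                    r = math.sqrt(r2)
                    mag = REP_K * (SIGMA_UNIT - r) / r
                    f_u[i, 0] += mag * dx
                    f_u[i, 1] += mag * dy
                    f_u[i, 2] += mag * dz
                    f_u[j, 0] -= mag * dx
                    f_u[j, 1] -= mag * dy
                    f_u[j, 2] -= mag * dz
        # complex bonds (spring, minus the repulsion wrongly added above)
        for b in range(bond_i.shape[0]):
            i = bond_i[b]
            j = bond_j[b]
            dx = unit_pos[i, 0] - unit_pos[j, 0]
            dy = unit_pos[i, 1] - unit_pos[j, 1]
            dz = unit_pos[i, 2] - unit_pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            mag = -BOND_K * (r - UNIT_BOND_NM) / r
            if r < SIGMA_UNIT:
                mag -= REP_K * (SIGMA_UNIT - r) / r  # undo pair repulsion
            f_u[i, 0] += mag * dx
            f_u[i, 1] += mag * dy
            f_u[i, 2] += mag * dz
            f_u[j, 0] -= mag * dx
            f_u[j, 1] -= mag * dy
            f_u[j, 2] -= mag * dz
        # complex angle stiffness, U = ANGLE_K * (1 + cos phi)
        for t in range(ang_a.shape[0]):
            ia = ang_a[t]
            ib = ang_b[t]
            ic = ang_c[t]
            ux = unit_pos[ia, 0] - unit_pos[ib, 0]
            uy = unit_pos[ia, 1] - unit_pos[ib, 1]
            uz = unit_pos[ia, 2] - unit_pos[ib, 2]
            ux -= box * round(ux / box)
            uy -= box * round(uy / box)
            uz -= box * round(uz / box)
            vx = unit_pos[ic, 0] - unit_pos[ib, 0]
            vy = unit_pos[ic, 1] - unit_pos[ib, 1]
            vz = unit_pos[ic, 2] - unit_pos[ib, 2]
            vx -= box * round(vx / box)
            vy -= box * round(vy / box)
            vz -= box * round(vz / box)
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = math.sqrt(lu2)
            lv = math.sqrt(lv2)
            dot = ux * vx + uy * vy + uz * vz
            cosphi = dot / (lu * lv)
            fax = -ANGLE_K * (vx / (lu * lv) - cosphi * ux / lu2)
            fay = -ANGLE_K * (vy / (lu * lv) - cosphi * uy / lu2)
            faz = -ANGLE_K * (vz / (lu * lv) - cosphi * uz / lu2)
            fcx = -ANGLE_K * (ux / (lu * lv) - cosphi * vx / lv2)
            fcy = -ANGLE_K * (uy / (lu * lv) - cosphi * vy / lv2)
            fcz = -ANGLE_K * (uz / (lu * lv) - cosphi * vz / lv2)
            f_u[ia, 0] += fax
            f_u[ia, 1] += fay
            f_u[ia, 2] += faz
            f_u[ic, 0] += fcx
            f_u[ic, 1] += fcy
            f_u[ic, 2] += fcz
            f_u[ib, 0] -= fax + fcx
            f_u[ib, 1] -= fay + fcy
            f_u[ib, 2] -= faz + fcz
        # DNA bonds
        for b in range(dna_i.shape[0]):
            i = dna_i[b]
            j = dna_j[b]
            dx = dna_flat[i, 0] - dna_flat[j, 0]
            dy = dna_flat[i, 1] - dna_flat[j, 1]
            dz = dna_flat[i, 2] - dna_flat[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            mag = -BOND_K * (r - DNA_BOND_NM) / r
            f_d[i, 0] += mag * dx
            f_d[i, 1] += mag * dy
            f_d[i, 2] += mag * dz
            f_d[j, 0] -= mag * dx
            f_d[j, 1] -= mag * dy
            f_d[j, 2] -= mag * dz
        # DNA bending stiffness (worm-like chain)
        for t in range(dang_a.shape[0]):
            ia = dang_a[t]
            ib = dang_b[t]
            ic = dang_c[t]
            ux = dna_flat[ia, 0] - dna_flat[ib, 0]
            uy = dna_flat[ia, 1] - dna_flat[ib, 1]
            uz = dna_flat[ia, 2] - dna_flat[ib, 2]
            ux -= box * round(ux / box)
            uy -= box * round(uy / box)
            uz -= box * round(uz / box)
            vx = dna_flat[ic, 0] - dna_flat[ib, 0]
            vy = dna_flat[ic, 1] - dna_flat[ib, 1]
            vz = dna_flat[ic, 2] - dna_flat[ib, 2]
            vx -= box * round(vx / box)
            vy -= box * round(vy / box)
            vz -= box * round(vz / box)
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = math.sqrt(lu2)
            lv = math.sqrt(lv2)
            cosphi = (ux * vx + uy * vy + uz * vz) / (lu * lv)
            fax = -DNA_ANGLE_K * (vx / (lu * lv) - cosphi * ux / lu2)
            fay = -DNA_ANGLE_K * (vy / (lu * lv) - cosphi * uy / lu2)
            faz = -DNA_ANGLE_K * (vz / (lu * lv) - cosphi * uz / lu2)
            fcx = -DNA_ANGLE_K * (ux / (lu * lv) - cosphi * vx / lv2)
            fcy = -DNA_ANGLE_K * (uy / (lu * lv) - cosphi * vy / lv2)
            fcz = -DNA_ANGLE_K * (uz / (lu * lv) - cosphi * vz / lv2)
            f_d[ia, 0] += fax
            f_d[ia, 1] += fay
            f_d[ia, 2] += faz
            f_d[ic, 0] += fcx
            f_d[ic, 1] += fcy
            f_d[ic, 2] += fcz
            f_d[ib, 0] -= fax + fcx
            f_d[ib, 1] -= fay + fcy
            f_d[ib, 2] -= faz + fcz
        # DNA-DNA soft repulsion
        for i in range(nd):
            for j in range(i + 1, nd):
                dx = dna_flat[i, 0] - dna_flat[j, 0]
                dy = dna_flat[i, 1] - dna_flat[j, 1]
                dz = dna_flat[i, 2] - dna_flat[j, 2]
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < SIGMA_DNA * SIGMA_DNA:
                    r = math.sqrt(r2)
                    mag = REP_K * (SIGMA_DNA - r) / r
                    f_d[i, 0] += mag * dx
                    f_d[i, 1] += mag * dy
                    f_d[i, 2] += mag * dz
                    f_d[j, 0] -= mag * dx
                    f_d[j, 1] -= mag * dy
                    f_d[j, 2] -= mag * dz
        for i in range(nu):
            for k in range(3):
                unit_pos[i, k] += f_u[i, k] * mob * dt + noise_u[step, i, k]
        for j in range(nd):
            for k in range(3):
                dna_flat[j, k] += f_d[j, k] * mob * dt + noise_d[step, j, k]


def run_dynamics(
    system: ReducedSystem,
    n_steps: int = 100_000,
    dt: float = 0.004,
    friction: float = 1.0,
    sample_stride: int = 250,
    seed: int | None = None,
) -> Trajectory:
    """Overdamped Langevin evolution with periodic wrapping.

    Positions advance by ``F * dt / friction`` plus Gaussian displacements of
    variance ``2 * T * dt / friction``.  Frames (units and DNA) are recorded
    every ``sample_stride`` steps; NaN/overflow aborts with the step index.
    """
    if dt * BOND_K / friction >= 1.9:
        raise ValueError("dt beyond the stability bound of the stiffest bond")
    rng = np.random.default_rng(system.seed + 1 if seed is None else seed)
    box = system.box_length
    unit_pos = system.unit_pos.copy()
    dna_flat = system.dna_pos.reshape(-1, 3).copy()
    depths = _bead_depths(system)
    L = system.dna_pos.shape[1]
    idx = np.arange(system.n_dna * L).reshape(system.n_dna, L)
    dna_i, dna_j = idx[:, 1:].ravel().copy(), idx[:, :-1].ravel().copy()
    if L >= 3:
        dang_a = idx[:, : L - 2].ravel().copy()
        dang_b = dang_a + 1
        dang_c = dang_a + 2
    else:
        dang_a = np.empty(0, dtype=int)
        dang_b = np.empty(0, dtype=int)
        dang_c = np.empty(0, dtype=int)
    if system.bond_pairs.size:
        bond_i = system.bond_pairs[:, 0].copy()
        bond_j = system.bond_pairs[:, 1].copy()
    else:
        bond_i = np.empty(0, dtype=int)
        bond_j = np.empty(0, dtype=int)
    if system.angle_triples.size:
        ang_a = system.angle_triples[:, 0].copy()
        ang_b = system.angle_triples[:, 1].copy()
        ang_c = system.angle_triples[:, 2].copy()
    else:
        ang_a = np.empty(0, dtype=int)
        ang_b = np.empty(0, dtype=int)
        ang_c = np.empty(0, dtype=int)

    mob = 1.0 / friction
    sigma_step = math.sqrt(2.0 * system.temperature * mob * dt)

    frames_u = [unit_pos % box]
    frames_d = [(dna_flat % box).reshape(system.n_dna, L, 3)]
    times = [0.0]
    done = 0
    while done < n_steps:
        chunk = min(sample_stride, n_steps - done)
        noise_u = sigma_step * rng.standard_normal((chunk, unit_pos.shape[0], 3))
        noise_d = sigma_step * rng.standard_normal((chunk, dna_flat.shape[0], 3))
        _chunk_steps(
            unit_pos, dna_flat, bond_i, bond_j, ang_a, ang_b, ang_c,
            dna_i, dna_j, dang_a, dang_b, dang_c, depths,
            box, dt, mob, noise_u, noise_d,
        )
        done += chunk
        if not (np.all(np.isfinite(unit_pos)) and np.all(np.isfinite(dna_flat))):
            raise FloatingPointError(f"non-finite coordinates at step {done}")
        frames_u.append(unit_pos % box)
        frames_d.append((dna_flat % box).reshape(system.n_dna, L, 3))
        times.append(done * dt)

    return Trajectory(
        times=np.array(times),
        unit_frames=np.array(frames_u),
        dna_frames=np.array(frames_d),
        box_length=box,
        motif_indices=system.motif_indices.copy(),
        contact_cutoff=system.contact_cutoff,
    )


# ---------------------------------------------------------------------------
# contact statistics


def count_contacts(
    unit_pos: np.ndarray,
    dna_pos: np.ndarray,
    motif_indices: np.ndarray,
    box_length: float,
    cutoff: float = CONTACT_CUTOFF_NM,
    mode: str = "dna",
) -> np.ndarray:
    """Per-chain count of units within the contact cutoff of the chain.

    ``mode="dna"`` counts a unit as contacting a chain when its minimum-image
    distance to any bead of that chain is <= cutoff (closed boundary);
    ``mode="motif"`` restricts the test to the chain's motif beads.
    """
    if mode == "motif":
        beads = dna_pos[:, np.asarray(motif_indices), :]
    elif mode == "dna":
        beads = dna_pos
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # (units, chains, beads)
    d = _min_image(unit_pos[:, None, None, :] - beads[None, :, :, :], box_length)
    r2 = np.einsum("ucbk,ucbk->ucb", d, d)
    contact = (r2.min(axis=2) <= cutoff**2)
    return contact.sum(axis=0)


def bound_distribution(
    trajectory: Trajectory, cutoff: float | None = None, mode: str = "dna"
) -> dict:
    """Bound-count histogram over the sampling half of a trajectory.

    The first half of the frames is discarded as equilibration; the rest
    contribute one count per chain per frame.
    """
    n_frames = trajectory.unit_frames.shape[0]
    if n_frames < 2:
        raise ValueError("trajectory too short: no sampling frames after equilibration")
    cutoff = trajectory.contact_cutoff if cutoff is None else cutoff
    start = n_frames // 2
    counts = np.stack(
        [
            count_contacts(
                trajectory.unit_frames[f],
                trajectory.dna_frames[f],
                trajectory.motif_indices,
                trajectory.box_length,
                cutoff,
                mode,
            )
            for f in range(start, n_frames)
        ]
    )
    flat = counts.ravel()
    hist = np.bincount(flat, minlength=int(flat.max()) + 2 if flat.size else 1)
    return {
        "counts": counts,
        "histogram": hist,
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=0)),
        "n_frames": counts.shape[0],
    }


def random_contact_expectation(
    n_units: int, n_beads_counted: int, box_length: float, cutoff: float = CONTACT_CUTOFF_NM
) -> dict:
    """Ideal-gas (zero-affinity) contact expectation for one chain.

    Contact spheres of non-adjacent beads do not overlap at the default
    geometry (bead spacing 3.4 nm > 2 * 1.2 nm), so the contact volume is
    additive: mean bound units per chain = n_units * n_beads * v / V, and
    the chance a chain has at least one bound unit is 1 - (1 - n*v/V)^units.
    """
    v = (4.0 / 3.0) * np.pi * cutoff**3
    p_unit = n_beads_counted * v / box_length**3
    return {
        "mean_per_chain": n_units * p_unit,
        "p_any": 1.0 - (1.0 - p_unit) ** n_units,
        "sd_per_chain": math.sqrt(n_units * p_unit * (1 - p_unit)),
    }


# ---------------------------------------------------------------------------
# Monte-Carlo mode (equilibrium cross-validation)


def metropolis_sample(
    system: ReducedSystem,
    n_sweeps: int = 20_000,
    max_step: float = 0.6,
    seed: int = 0,
    record_every: int = 10,
) -> np.ndarray:
    """Metropolis sampling of unit positions against frozen DNA.

    Single-unit displacement moves, uniform in a cube of half-width
    ``max_step``.  Returns recorded unit-position frames (F, n_units, 3).
    """
    rng = np.random.default_rng(seed)
    box = system.box_length
    pos = system.unit_pos.copy()
    beta = 1.0 / system.temperature
    e = unit_energy(pos, system)
    frames = []
    n = pos.shape[0]
    for sweep in range(n_sweeps):
        for _ in range(n):
            k = int(rng.integers(n))
            trial = pos.copy()
            trial[k] = (trial[k] + rng.uniform(-max_step, max_step, 3)) % box
            e_new = unit_energy(trial, system)
            if e_new <= e or rng.random() < math.exp(-beta * (e_new - e)):
                pos, e = trial, e_new
        if sweep % record_every == 0:
            frames.append(pos.copy())
    return np.array(frames)


# ---------------------------------------------------------------------------
# oligomer-state scan


def scan_oligomer_states(
    states=(1, 2, 3, 4, 5),
    seeds=(0, 1, 2),
    n_steps: int = 100_000,
    mode: str = "dna",
    progress: bool = False,
    **build_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Mean bound units per chain versus oligomeric state.

    Runs ``len(states) * len(seeds)`` seeded simulations, pools the per-seed
    means per state, and reports the Spearman rank correlation between state
    and per-state mean as the monotonicity statistic.  A single seed leaves
    the SD undefined (NaN) and is flagged in the summary.
    """
    states = list(states)
    seeds = list(seeds)
    if len(states) < 2:
        raise ValueError("need at least 2 oligomer states")
    rows = []
    for s in states:
        for sd in seeds:
            system = build_system(s, seed=int(sd), **build_kwargs)
            traj = run_dynamics(system, n_steps=n_steps, seed=int(sd) * 7919 + 11)
            dist = bound_distribution(traj, mode=mode)
            rows.append(
                {
                    "oligomer_state": s,
                    "seed": int(sd),
                    "mean_bound": dist["mean"],
                    "sd_bound": dist["sd"],
                    "remainder_monomers": system.n_remainder_monomers,
                }
            )
            if progress:
                print(f"state {s} seed {sd}: mean bound {dist['mean']:.3f}")
    table = pd.DataFrame(rows)
    per_state = table.groupby("oligomer_state")["mean_bound"].agg(["mean", "std", "count"])
    rho, pval = spearmanr(per_state.index.values, per_state["mean"].values)
    summary = {
        "per_state_mean": per_state["mean"].to_dict(),
        "per_state_sd": per_state["std"].to_dict(),
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "single_seed": len(seeds) < 2,
    }
    return table, summary
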