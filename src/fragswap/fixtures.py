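"""Deterministic synthetic-data generators for every toolkit input.

Each generator takes an explicit integer seed, returns the in-memory
object plus a "truth" dict of the planted parameters, and is
byte-deterministic for a fixed seed (NumPy Generator with integer
seeding).  Downstream fits and detectors are validated against the
planted truth; library code never reads truth records.

What is emulated and what is not: sequences evolve by uniform
substitution with coil-restricted indels (no rate heterogeneity or
structure-aware substitution models); assay noise is multiplicative
Gaussian for rates and additive on the percent scale for thermal curves
(truncated to [0, 110]%); trajectory frames place planted donor/
hydrogen/acceptor triples in ideal linear geometry rather than
force-field-realistic ensembles.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .align_ss import SecondaryStructureString
from .errors import InputError
from .formats_io import AssayTable, Atom, SeqRecord, StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# parent pairs


def make_parent_pair(
    seed: int,
    length: int,
    ss_layout: str,
    divergence_pct: float = 47.0,
    indels: int = 0,
) -> tuple[SeqRecord, SeqRecord, SecondaryStructureString, SecondaryStructureString, dict]:
    """A homologous parent pair sharing a secondary-structure layout.

    Parent A is random; parent B substitutes ``divergence_pct`` percent
    of positions (always to a different residue) and deletes ``indels``
    residues, each from the interior of a distinct coil run, so
    structure elements are never disturbed.  The default divergence
    places the pair in the ~53% identity regime typical of swap-
    compatible GH10 homolog pairs.
    """
    if len(ss_layout) != length:
        raise InputError("ss_layout length must equal sequence length")
    if not 0 <= divergence_pct <= 100:
        raise InputError("divergence_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    n_sub = int(round(divergence_pct / 100.0 * length))
    sub_positions = sorted(rng.choice(length, size=n_sub, replace=False).tolist())
    seq_b = list(seq_a)
    for pos in sub_positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq_b[pos]]
        seq_b[pos] = alternatives[int(rng.integers(len(alternatives)))]
    ss_b = list(ss_layout)
    if indels:
        interior = [
            i
            for i in range(1, length - 1)
            if ss_layout[i] == "C" and ss_layout[i - 1] == "C" and ss_layout[i + 1] == "C"
        ]
        if len(interior) < indels:
            raise InputError(
                f"cannot place {indels} indel(s): only {len(interior)} interior coil positions"
            )
        chosen = sorted(rng.choice(interior, size=indels, replace=False).tolist(), reverse=True)
        for pos in chosen:
            del seq_b[pos]
            del ss_b[pos]
    a = SeqRecord(id="parentA", seq=seq_a)
    b = SeqRecord(id="parentB", seq="".join(seq_b))
    truth = {
        "seed": seed,
        "length": length,
        "divergence_pct": divergence_pct,
        "n_substitutions": n_sub,
        "indels": indels,
    }
    return a, b, SecondaryStructureString(ss_layout), SecondaryStructureString("".join(ss_b)), truth


def ten_fragment_layout() -> str:
    """An SS layout with nine interior coil gaps wide enough that a
    ten-fragment demarcation (target_count 10) is feasible under the
    default length rules."""
    return "C" * 6 + ("H" * 10 + "C" * 4) * 9 + "C" * 2


# ---------------------------------------------------------------------------
# ideal-geometry backbones

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position D given three predecessors,
    a bond length C-D, angle B-C-D, and torsion A-B-C-D."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: Sequence[tuple[float, float]], chain: str = "A", res_name: str = "ALA") -> StructureModel:
    """N/CA/C backbone from a list of per-residue (phi, psi) in degrees.

    phi of the first residue and psi of the last are undefined and
    ignored; the peptide bond omega is fixed at 180 deg.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise InputError("need at least 2 residues")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_next = _place_atom(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    atoms = [
        Atom(chain=chain, res_seq=i + 1, res_name=res_name, atom_name=name, x=float(p[0]), y=float(p[1]), z=float(p[2]))
        for i, res in enumerate(coords)
        for name, p in res.items()
    ]
    return StructureModel(model_index=0, atoms=atoms, source="synthetic backbone")


def make_helix_coords(n_res: int = 12, phi: float = -57.0, psi: float = -47.0) -> tuple[StructureModel, str, dict]:
    """Ideal alpha-helical backbone; truth label caps the termini as coil
    because terminal residues lack a full (phi, psi) pair."""
    model = build_backbone([(phi, psi)] * n_res)
    interior = n_res - 2
    truth_ss = "C" + ("H" * interior if interior >= 4 else "C" * interior) + "C"
    return model, truth_ss, {"phi": phi, "psi": psi, "n_res": n_res}


def make_strand_coords(n_res: int = 10, phi: float = -120.0, psi: float = 120.0) -> tuple[StructureModel, str, dict]:
    """Ideal extended-strand backbone with coil-capped truth label."""
    model = build_backbone([(phi, psi)] * n_res)
    interior = n_res - 2
    truth_ss = "C" + ("E" * interior if interior >= 3 else "C" * interior) + "C"
    return model, truth_ss, {"phi": phi, "psi": psi, "n_res": n_res}


# ---------------------------------------------------------------------------
# assay datasets

DEFAULT_S_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 10.0)  # mg/mL, within the 0.5-10 assay design


def make_kinetics(
    seed: int,
    km: float = 0.75,
    vmax: float = 680.0,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    noise_cv: float = 0.0,
) -> tuple[AssayTable, dict]:
    """Substrate-vs-rate table from a Michaelis-Menten curve with
    multiplicative Gaussian noise of the given coefficient of variation."""
    if km <= 0 or vmax <= 0:
        raise InputError("Km and Vmax must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(s_grid, dtype=float)
    v = vmax * s / (km + s)
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.standard_normal(len(s)))
        v = np.clip(v, 1e-9, None)
    table = AssayTable(
        kind="kinetics",
        data=pd.DataFrame({"substrate_mg_per_mL": s, "rate": v}),
        metadata={"generator": "make_kinetics", "seed": str(seed)},
    )
    return table, {"seed": seed, "km": km, "vmax": vmax, "noise_cv": noise_cv}


def make_t50(
    seed: int,
    t50: float = 66.5,
    slope: float = 2.0,
    temps: Sequence[float] | None = None,
    noise_sd: float = 0.0,
) -> tuple[AssayTable, dict]:
    """Residual-activity-vs-temperature table from a 2-parameter logistic,
    additive Gaussian noise on the percent scale truncated to [0, 110]."""
    rng = np.random.default_rng(seed)
    t = np.asarray(temps if temps is not None else np.arange(30.0, 80.5, 2.5), dtype=float)
    r = 100.0 / (1.0 + np.exp((t - t50) / slope))
    if noise_sd > 0:
        r = np.clip(r + noise_sd * rng.standard_normal(len(t)), 0.0, 110.0)
    table = AssayTable(
        kind="thermal_T50",
        data=pd.DataFrame({"temperature_C": t, "residual_pct": r}),
        metadata={"generator": "make_t50", "seed": str(seed)},
    )
    return table, {"seed": seed, "t50": t50, "slope": slope, "noise_sd": noise_sd}


def make_decay(
    seed: int,
    t_half: float = 1.2,
    times: Sequence[float] | None = None,
    noise_sd: float = 0.0,
) -> tuple[AssayTable, dict]:
    """First-order inactivation timecourse with planted half-life (h)."""
    if t_half <= 0:
        raise InputError("t_half must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.arange(0.0, 4.25, 0.5), dtype=float)
    k = math.log(2.0) / t_half
    r = 100.0 * np.exp(-k * t)
    if noise_sd > 0:
        r = np.clip(r + noise_sd * rng.standard_normal(len(t)), 1e-6, 110.0)
    table = AssayTable(
        kind="thermal_decay",
        data=pd.DataFrame({"time_h": t, "residual_pct": r}),
        metadata={"generator": "make_decay", "seed": str(seed)},
    )
    return table, {"seed": seed, "t_half": t_half, "k": k, "noise_sd": noise_sd}


def make_synergy(
    seed: int,
    times: Sequence[float] | None = None,
    ds_profile: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None,
    cellulase_15h: float = 3.2,
    xylanase_15h: float = 0.45,
    control_level: float = 0.02,
) -> tuple[AssayTable, dict]:
    """Co-hydrolysis timecourse parameterized directly by a target DS(t).

    Single-enzyme arms follow saturating release curves scaled to their
    15-h values; the simultaneous arm is constructed as
    DS(t) x (Y_cellulase + Y_xylanase), so the degree-of-synergy
    analysis has a closed-form oracle.
    """
    t = np.asarray(times if times is not None else np.arange(1.0, 16.0), dtype=float)
    if ds_profile is None:
        ds = 1.0 + 0.068 * t / 15.0  # gentle rise to 1.068 at 15 h
    elif callable(ds_profile):
        ds = np.asarray(ds_profile(t), dtype=float)
    else:
        ds = np.asarray(ds_profile, dtype=float)
        if len(ds) != len(t):
            raise InputError("ds_profile length must match the time grid")
    half_time = 5.0  # h, release half-saturation
    shape = t / (half_time + t)
    shape_15 = 15.0 / (half_time + 15.0)
    y_cel = cellulase_15h * shape / shape_15
    y_xyl = xylanase_15h * shape / shape_15
    y_both = ds * (y_cel + y_xyl)
    ctrl = np.full_like(t, control_level)
    table = AssayTable(
        kind="synergy",
        data=pd.DataFrame(
            {
                "time_h": t,
                "cellulase_only": y_cel,
                "xylanase_only": y_xyl,
                "both": y_both,
                "control": ctrl,
            }
        ),
        metadata={"generator": "make_synergy", "seed": str(seed)},
    )
    truth = {"seed": seed, "ds": ds.tolist(), "cellulase_15h": cellulase_15h, "xylanase_15h": xylanase_15h}
    return table, truth


# ---------------------------------------------------------------------------
# trajectories with planted hydrogen bonds


def make_trajectory(
    seed: int,
    n_frames: int = 20,
    bond_schedule: dict[int, set[int]] | None = None,
    n_decoys: int = 10,
    decoy_spacing: float = 8.0,
) -> tuple[list[StructureModel], dict]:
    """Multi-frame structure with hydrogen bonds planted on schedule.

    ``bond_schedule`` maps a planted-pair index to the set of frame
    indices where that pair is bonded (2.9 A, linear D-H...A); in all
    other frames the acceptor is displaced to 6 A.  Decoy residues carry
    catalogued donor/acceptor atoms but sit ``decoy_spacing`` apart, far
    outside the criteria.
    """
    if bond_schedule is None:
        bond_schedule = {0: set(range(n_frames))}
    if any(f >= n_frames or f < 0 for frames in bond_schedule.values() for f in frames):
        raise InputError("bond_schedule frame index out of range")
    if decoy_spacing <= 4.0:
        raise InputError(f"decoy_spacing {decoy_spacing} too dense: decoys would satisfy the criteria")
    pair_ids = sorted(bond_schedule)
    frames: list[StructureModel] = []
    truth_pairs = {}
    for frame_idx in range(n_frames):
        atoms: list[Atom] = []
        for slot, pair_id in enumerate(pair_ids):
            x0 = 30.0 * slot
            donor_seq = 100 + 2 * pair_id
            acceptor_seq = donor_seq + 1
            bonded = frame_idx in bond_schedule[pair_id]
            acc_x = x0 + 2.9 if bonded else x0 + 6.0
            atoms.append(Atom("A", donor_seq, "SER", "OG", x0, 0.0, 0.0))
            atoms.append(Atom("A", donor_seq, "SER", "HG", x0 + 1.0, 0.0, 0.0))
            atoms.append(Atom("A", acceptor_seq, "GLU", "OE2", acc_x, 0.0, 0.0))
            truth_pairs[pair_id] = {
                "donor": f"S_{donor_seq}@OG",
                "acceptor": f"E_{acceptor_seq}@OE2",
                "bonded_frames": sorted(bond_schedule[pair_id]),
            }
        for d in range(n_decoys):
            # alternate donor-bearing and acceptor-bearing decoy residues
            res_seq = 500 + d
            x = decoy_spacing * d
            if d % 2 == 0:
                atoms.append(Atom("A", res_seq, "THR", "OG1", x, 50.0, 0.0))
                atoms.append(Atom("A", res_seq, "THR", "HG1", x + 1.0, 50.0, 0.0))
            else:
                atoms.append(Atom("A", res_seq, "ASP", "OD1", x, 50.0, 0.0))
        frames.append(StructureModel(model_index=frame_idx + 1, atoms=atoms, source="synthetic trajectory"))
    truth = {"seed": seed, "n_frames": n_frames, "pairs": truth_pairs, "n_decoys": n_decoys}
    return frames, truth
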