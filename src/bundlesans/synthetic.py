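"""Ground-truth synthetic scattering data for every analysis stage.

Each generator evaluates an exact model intensity on a Q grid and adds
Q-dependent counting noise,

    sigma(Q) = I(Q) * (floor + k / sqrt(I(Q) * t_eff)),

a Gaussian stand-in for the error bars of a background-subtracted SANS
measurement of a ~5 mg/mL protein solution.  The defaults (1% relative
floor, counting coefficient chosen so sigma/I reaches ~3% at the high-Q
end of a typical curve on the absolute scale I(0) ~ 0.1 cm^-1) emulate
the noise structure of reduced beamline data; they do not emulate
instrument smearing, inter-detector merging artifacts or systematic
background errors.

Ground truth travels with the curve: :func:`generate_curve` returns it as
a dict, and :func:`generate_to_files` writes it as a sidecar JSON next to
the .dat so nothing downstream parses truth out of filenames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import special

from .atomistic import AtomicModel, ContrastModel, debye_sum_curve
from .joint_clubs import JointClubsParams, joint_clubs_intensity
from .model_free import debye_function
from .sas_io import ScatteringCurve, write_curve

__all__ = [
    "SyntheticSpec", "generate_curve", "generate_to_files",
    "generate_bundle_scenarios", "sphere_intensity", "cylinder_intensity",
    "sphere_pr", "build_ideal_helix",
]

MODELS = ("sphere", "gaussian_coil", "cylinder", "joint_clubs",
          "atomistic", "two_population")

# default grid: the usable SANS window (0.05-0.25 1/A) plus low-Q Guinier
# coverage down to 0.01 1/A and high-Q Kratky coverage up to 0.4 1/A
DEFAULT_GRID = (0.01, 0.4, 120, "linear")
NOISE_FLOOR = 0.01
NOISE_COUNTING_K = 0.0013   # sigma/I ~ 3% at Q = 0.25 1/A for I(0) ~ 0.1
NOISE_T_EFF = 1.0


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic curve: model + parameters + grid + noise."""
    model: str
    params: Dict = field(default_factory=dict)
    q_grid: Tuple[float, float, int, str] = DEFAULT_GRID
    noise_floor: float = NOISE_FLOOR
    noise_counting_k: float = NOISE_COUNTING_K
    noise_t_eff: float = NOISE_T_EFF
    seed: int = 0
    label: str = ""
    concentration: Optional[float] = None
    pd_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {MODELS}")
        qmin, qmax, n, spacing = self.q_grid
        if qmin <= 0 or qmax <= qmin:
            raise ValueError("need 0 < qmin < qmax")
        if n < 20:
            raise ValueError("need >= 20 grid points")
        if spacing not in ("linear", "log"):
            raise ValueError("grid spacing must be 'linear' or 'log'")
        if self.noise_floor < 0 or self.noise_counting_k < 0:
            raise ValueError("noise coefficients must be >= 0")

    def make_grid(self) -> np.ndarray:
        qmin, qmax, n, spacing = self.q_grid
        if spacing == "log":
            return np.geomspace(qmin, qmax, n)
        return np.linspace(qmin, qmax, n)


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Uniform-sphere form factor I(Q) = I0 [3 (sin x - x cos x)/x^3]^2."""
    x = np.asarray(q, dtype=float) * radius
    out = np.ones_like(x)
    nz = x > 1e-8
    out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
    return i0 * out


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Normalized pair-distance distribution of a uniform sphere,
    p(r) ~ r^2 (1 - 3r/4R + r^3/16R^3) on [0, 2R] (peak scaled to 1)."""
    r = np.asarray(r, dtype=float)
    x = r / radius
    p = np.where(r <= 2 * radius,
                 r ** 2 * (1.0 - 0.75 * x + x ** 3 / 16.0), 0.0)
    p = np.clip(p, 0.0, None)
    peak = p.max() if p.max() > 0 else 1.0
    return p / peak


def cylinder_intensity(q: np.ndarray, length: float, diameter: float,
                       i0: float = 1.0, n_quad: int = 256) -> np.ndarray:
    """Orientationally averaged cylinder form factor by Gauss-Legendre
    quadrature over the axis angle (exact up to quadrature error)."""
    radius = diameter / 2.0
    x, w = np.polynomial.legendre.leggauss(n_quad)
    # map to alpha in (0, pi/2): integrate over cos(alpha) in (0, 1)
    mu = 0.5 * (x + 1.0)
    wq = 0.5 * w
    q = np.asarray(q, dtype=float)
    out = np.empty_like(q)
    for i, qi in enumerate(q):
        a = qi * mu * length / 2.0
        sin_t = np.sqrt(1.0 - mu ** 2)
        b = qi * sin_t * radius
        sa = np.where(np.abs(a) > 1e-12, np.sin(a) / np.where(a == 0, 1, a), 1.0)
        cb = np.where(np.abs(b) > 1e-12, 2.0 * special.j1(b) / np.where(b == 0, 1, b), 1.0)
        out[i] = np.sum(wq * (sa * cb) ** 2)
    return i0 * out


def _two_population_intensity(q, rg_m, rg_a, i0_m, i0_a):
    return (i0_m * np.exp(-q ** 2 * rg_m ** 2 / 3.0)
            + i0_a * np.exp(-q ** 2 * rg_a ** 2 / 3.0))


def _exact_intensity(spec: SyntheticSpec, q: np.ndarray) -> Tuple[np.ndarray, Dict]:
    p = spec.params
    if spec.model == "sphere":
        radius, i0 = p.get("radius", 25.82), p.get("i0", 1.0)
        inten = sphere_intensity(q, radius, i0) + p.get("flat_background", 0.0)
        truth = {"radius": radius, "i0": i0,
                 "rg": float(np.sqrt(3.0 / 5.0) * radius)}
    elif spec.model == "gaussian_coil":
        rg, i0 = p.get("rg", 25.0), p.get("i0", 1.0)
        inten = i0 * debye_function(q, rg) + p.get("flat_background", 0.0)
        truth = {"rg": rg, "i0": i0}
    elif spec.model == "cylinder":
        L, R, i0 = p.get("length", 31.5), p.get("diameter", 10.6), p.get("i0", 1.0)
        inten = cylinder_intensity(q, L, R, i0)
        truth = {"length": L, "diameter": R, "i0": i0,
                 "rg": float(np.sqrt(L ** 2 / 12.0 + (R / 2.0) ** 2 / 2.0))}
    elif spec.model == "joint_clubs":
        params = p.get("params") or JointClubsParams(
            n_clubs=p.get("n_clubs", 4), club_length=p.get("length", 31.5),
            club_diameter=p.get("diameter", 10.6),
            loop_gap=p.get("loop_gap", 5.0),
            scale=p.get("i0", 1.0), background=p.get("background", 0.0))
        n_conf = p.get("n_conformations", 20000)
        tc = joint_clubs_intensity(params, q, n_conformations=n_conf,
                                   seed=spec.seed)
        inten = tc.intensity
        truth = {"length": params.club_length, "diameter": params.club_diameter,
                 "n_clubs": params.n_clubs, "i0": params.scale,
                 "loop_gap": params.loop_gap}
    elif spec.model == "atomistic":
        model: AtomicModel = p["model"]
        contrast = p.get("contrast") or ContrastModel()
        tc = debye_sum_curve(model, contrast, q)
        i0 = p.get("i0")
        scale = i0 / tc.intensity[0] if i0 else 1.0
        inten = tc.intensity * scale
        truth = {"n_atoms": len(model), "i0": float(inten[0])}
    elif spec.model == "two_population":
        rg_m = p.get("rg_monomer", 18.0)
        rg_a = p.get("rg_aggregate", 100.0)
        i0_m = p.get("i0_monomer", 1.0)
        number_fraction = p.get("number_fraction", 0.002)
        # per-particle I(0) ~ V^2 ~ rg^6: convert the number fraction into
        # the aggregate's forward intensity
        n_ratio = number_fraction / (1.0 - number_fraction)
        i0_a = i0_m * n_ratio * (rg_a / rg_m) ** 6
        inten = _two_population_intensity(q, rg_m, rg_a, i0_m, i0_a)
        truth = {"rg_monomer": rg_m, "rg_aggregate": rg_a, "i0_monomer": i0_m,
                 "i0_aggregate": float(i0_a),
                 "number_fraction": number_fraction}
    else:  # pragma: no cover — guarded in __post_init__
        raise ValueError(spec.model)
    return inten, truth


def generate_curve(spec: SyntheticSpec) -> Tuple[ScatteringCurve, Dict]:
    """Generate a noisy curve and its ground-truth record."""
    q = spec.make_grid()
    inten, truth = _exact_intensity(spec, q)
    ipos = np.clip(inten, 1e-12, None)
    sigma = ipos * (spec.noise_floor
                    + spec.noise_counting_k / np.sqrt(ipos * spec.noise_t_eff))
    rng = np.random.default_rng(spec.seed)
    noisy = inten + rng.standard_normal(len(q)) * sigma
    truth = dict(truth)
    truth.update({"model": spec.model, "seed": spec.seed,
                  "noise_floor": spec.noise_floor,
                  "noise_counting_k": spec.noise_counting_k})
    curve = ScatteringCurve(q=q, intensity=noisy,
                            sigma=sigma if (spec.noise_floor > 0
                                            or spec.noise_counting_k > 0)
                            else None,
                            label=spec.label or spec.model,
                            concentration=spec.concentration,
                            pd_value=spec.pd_value)
    return curve, truth


def generate_to_files(spec: SyntheticSpec, dat_path) -> Tuple[Path, Path]:
    """Write the generated curve as .dat plus a ground-truth sidecar JSON."""
    dat_path = Path(dat_path)
    curve, truth = generate_curve(spec)
    write_curve(curve, dat_path)
    truth_path = dat_path.with_suffix(dat_path.suffix + ".truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return dat_path, truth_path


# the four solution states the pD series walks through; intensities on the
# absolute-scale footing I(0)/C proportional to molecular weight, with the
# standard (random-coil monomer) at I(0) = 0.078, C = 5.5 mg/mL
_SCENARIOS = {
    "pD 1.7": dict(conc=5.5, mw_mult=1.0, pd=1.7),
    "pD 6.4": dict(conc=5.5, mw_mult=2.0, pd=6.4),
    "pD 9.6": dict(conc=5.3, mw_mult=1.9, pd=9.6),
    "pD ~13": dict(conc=5.3, mw_mult=1.0, pd=13.0),
}
_I0_PER_C_MONOMER = 0.078 / 5.5
_RG_COIL = 25.0      # A, random-coil monomer
_RG_DIMER = 18.0     # A, compact folded dimer
_RG_MONO = 14.0      # A, compact folded monomer
_FLAT_FLOOR = 2e-4   # residual incoherent floor under the folded states


def generate_bundle_scenarios(
    seed: int = 0, n_conformations: int = 20000,
) -> Dict[str, Tuple[ScatteringCurve, Dict]]:
    """Four labeled curves emulating the pD series of a helix-bundle protein.

    (i)   "pD 1.7": Gaussian-coil monomer, Rg 25 A (the MW standard);
    (ii)  "pD 6.4": compact folded dimer, Rg 18 A;
    (iii) "pD 9.6": 9:1 intensity-weighted dimer:monomer mixture;
    (iv)  "pD ~13": joint-clubs open bundle (n=4, L=31.5 A, R=10.6 A).

    Forward intensities are scaled so the dimer:monomer I(0)/C ratio is 2,
    the signature the molecular-weight assignment relies on.
    """
    out = {}
    for i, (label, meta) in enumerate(_SCENARIOS.items()):
        i0 = _I0_PER_C_MONOMER * meta["conc"] * meta["mw_mult"]
        common = dict(seed=seed + i, label=label, concentration=meta["conc"],
                      pd_value=meta["pd"])
        if label == "pD 1.7":
            spec = SyntheticSpec("gaussian_coil",
                                 {"rg": _RG_COIL, "i0": i0}, **common)
        elif label == "pD 6.4":
            radius = _RG_DIMER / np.sqrt(3.0 / 5.0)
            spec = SyntheticSpec("sphere", {"radius": radius, "i0": i0,
                                            "flat_background": _FLAT_FLOOR},
                                 **common)
        elif label == "pD 9.6":
            out[label] = _globule_mixture_curve(i0, **common)
            continue
        else:
            spec = SyntheticSpec(
                "joint_clubs",
                {"length": 31.5, "diameter": 10.6, "n_clubs": 4, "i0": i0,
                 "n_conformations": n_conformations},
                **common)
        out[label] = generate_curve(spec)
    return out


def _globule_mixture_curve(i0, seed, label, concentration, pd_value):
    """Scenario (iii): a 9:1 dimer:monomer forward-intensity mixture of two
    compact globules plus the incoherent floor — partial dissociation."""
    q = np.linspace(*DEFAULT_GRID[:3])
    r_dim = _RG_DIMER / np.sqrt(3.0 / 5.0)
    r_mon = _RG_MONO / np.sqrt(3.0 / 5.0)
    inten = (0.9 * i0 * sphere_intensity(q, r_dim)
             + 0.1 * i0 * sphere_intensity(q, r_mon) + _FLAT_FLOOR)
    ipos = np.clip(inten, 1e-12, None)
    sigma = ipos * (NOISE_FLOOR + NOISE_COUNTING_K / np.sqrt(ipos))
    rng = np.random.default_rng(seed)
    noisy = inten + rng.standard_normal(len(q)) * sigma
    curve = ScatteringCurve(q=q, intensity=noisy, sigma=sigma, label=label,
                            concentration=concentration, pd_value=pd_value)
    truth = {"model": "globule_mixture", "i0": float(i0),
             "rg_dimer": _RG_DIMER, "rg_monomer": _RG_MONO,
             "dimer_weight": 0.9, "seed": seed}
    return curve, truth


# --- synthetic atomic geometry -------------------------------------------

_HELIX_RISE = 1.5       # A per residue along the axis
_HELIX_RADIUS = 2.3     # A, C-alpha circle radius of an ideal alpha-helix
_HELIX_TWIST = 100.0    # degrees per residue


def build_ideal_helix(n_res: int, chain_id: str = "A", first_res: int = 1,
                      axis_origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                      rise: float = _HELIX_RISE,
                      radius: float = _HELIX_RADIUS) -> AtomicModel:
    """Ideal straight alpha-helix of C-alpha (and dummy backbone) atoms.

    Places CA atoms on a helix of the given rise, radius and 100 deg/res
    twist, plus N, C, O atoms at small offsets so that diameter metrics
    have backbone atoms to work with.  Residues are alanines.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    origin = np.asarray(axis_origin, float)
    names, elements, resn, resi, chain, coords = [], [], [], [], [], []
    for i in range(n_res):
        ang = np.radians(_HELIX_TWIST * i)
        radial = np.cos(ang) * e1 + np.sin(ang) * e2
        ca = origin + rise * i * axis + radius * radial
        # simple backbone placements near the CA
        # backbone atoms sit close to the C-alpha radius in a real helix;
        # offsets are mostly axial so radial metrics reflect the build radius
        offsets = {"N": -0.6 * axis + 0.1 * radial,
                   "CA": 0.0 * axis,
                   "C": 0.6 * axis + 0.1 * radial,
                   "O": 0.9 * axis + 0.2 * radial}
        for name, off in offsets.items():
            names.append(name)
            elements.append(name[0])
            resn.append("ALA")
            resi.append(first_res + i)
            chain.append(chain_id)
            coords.append(ca + off if name != "CA" else ca)
    return AtomicModel(element=np.array(elements), atom_name=np.array(names),
                       res_name=np.array(resn),
                       res_seq=np.array(resi, dtype=int),
                       chain_id=np.array(chain),
                       coords=np.array(coords), assembly="asis")
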