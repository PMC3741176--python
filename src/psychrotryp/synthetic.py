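"""Seeded generators for thermokinetic, structural and gel-band test data.

The generators emulate the statistical structure the analysis assumes:

* activity–temperature curves that are Arrhenius below the optimum and fall
  off above it through a two-state thermal-inactivation equilibrium, with
  multiplicative lognormal measurement noise;
* psychrophile/mesophile enzyme pairs differing by planted activation
  enthalpy/entropy differentials (defaults reproduce a ddG of about
  -1.35 kJ/mol at 20 degC, i.e. a ~1.7-fold advantage, growing to ~4-fold at
  10 degC);
* proteins with planted K/R cleavage sites, disulfide topologies,
  catalytic-triad positions and per-residue exposure values engineered so
  that exactly the intended sites pass the lability filter;
* gel-band observations: true disulfide-group masses with Gaussian error,
  with sub-5-kDa species dropped (they migrate out of the gel).

Every generator is a pure function of its spec and seed (numpy
``default_rng``), so outputs are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autolysis import (
    BandObservation,
    CleavagePattern,
    DisulfideTopology,
    ProteinChain,
    Tag,
    fragment_groups,
    group_mass,
)
from .constants import CODATA, THREE_TO_ONE, PhysicalConstants
from .structure import Atom, ContactAnnotation, ExposureProfile, Structure
from .thermokinetics import ActivityTemperatureSeries

__all__ = [
    "EnzymeSimSpec",
    "ProteinFixtureSpec",
    "ProteinFixture",
    "simulate_activity_series",
    "simulate_enzyme_pair",
    "simulate_protein_fixture",
    "simulate_gel_bands",
    "build_extended_peptide",
]

DEFAULT_TEMPERATURES = tuple(float(t) for t in np.arange(277.15, 353.16, 2.0))

# Background alphabet excludes K/R (no accidental sites), C (no stray
# cysteines) and P (no accidental proline suppression of a planted site).
_BACKGROUND_AA = "ADEFGHILMNQSTVWY"


@dataclass(frozen=True)
class EnzymeSimSpec:
    """Parameters of one simulated enzyme's activity-temperature curve.

    ``lnA`` and ``Ea`` (J/mol) set the Arrhenius limb; ``T_m`` (K) and
    ``dH_u`` (J/mol) the two-state inactivation equilibrium producing the
    descending limb; ``noise_sigma`` the lognormal measurement error.
    Defaults describe a mesophilic reference with Ea = 75 kJ/mol and
    k(293.15 K) = 1 /s, unfolding near 55 degC. The default Ea exceeds the
    magnitude of the default planted activation-enthalpy differential
    (-57.4 kJ/mol), so the derived psychrophile keeps a physically sensible
    positive apparent activation energy.
    """

    label: str = "meso"
    substrate: str = "BAPNA"
    lnA: float = 30.7716
    Ea: float = 75_000.0
    T_m: float = 328.0
    dH_u: float = 400_000.0
    noise_sigma: float = 0.0
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    seed: int = 0
    unit_tag: str = "s^-1"

    def __post_init__(self) -> None:
        if self.Ea <= 0:
            raise ValueError("Ea must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.temperatures) == 0:
            raise ValueError("no temperatures")
        if self.T_m < min(self.temperatures):
            raise ValueError("T_m must lie inside or above the temperature grid")


def _prenoise_rates(spec: EnzymeSimSpec, constants: PhysicalConstants = CODATA) -> np.ndarray:
    t = np.asarray(spec.temperatures, dtype=float)
    arr = np.exp(spec.lnA - spec.Ea / (constants.R * t))
    f_active = 1.0 / (1.0 + np.exp(-(spec.dH_u / constants.R) * (1.0 / t - 1.0 / spec.T_m)))
    return arr * f_active


def simulate_activity_series(
    spec: EnzymeSimSpec, constants: PhysicalConstants = CODATA
) -> ActivityTemperatureSeries:
    """rate(T) = exp(lnA - Ea/RT) * f_active(T), with lognormal noise."""
    rates = _prenoise_rates(spec, constants)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        rates = rates * rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=rates.size)
    return ActivityTemperatureSeries(
        enzyme_label=spec.label,
        substrate_label=spec.substrate,
        temperatures=tuple(spec.temperatures),
        rates=tuple(float(r) for r in rates),
        unit_tag=spec.unit_tag,
    )


def simulate_enzyme_pair(
    ddH: float = -57_400.0,
    ddS: float = -191.2,
    meso_spec: EnzymeSimSpec = EnzymeSimSpec(),
    psychro_label: str = "psychro",
    constants: PhysicalConstants = CODATA,
) -> tuple[ActivityTemperatureSeries, ActivityTemperatureSeries]:
    """A psychrophile/mesophile pair with planted activation differentials.

    Pre-noise psychrophile rates are the mesophile's scaled pointwise by
    exp(-(ddH - T*ddS)/(R*T)); both series then receive independent noise
    draws from one seeded stream, so identical seeds give identical pairs.
    """
    t = np.asarray(meso_spec.temperatures, dtype=float)
    meso_rates = _prenoise_rates(meso_spec, constants)
    factor = np.exp(-(ddH - t * ddS) / (constants.R * t))
    psychro_rates = meso_rates * factor
    if meso_spec.noise_sigma > 0:
        rng = np.random.default_rng(meso_spec.seed)
        meso_rates = meso_rates * rng.lognormal(0.0, meso_spec.noise_sigma, t.size)
        psychro_rates = psychro_rates * rng.lognormal(0.0, meso_spec.noise_sigma, t.size)
    mk = dict(
        substrate_label=meso_spec.substrate,
        temperatures=tuple(meso_spec.temperatures),
        unit_tag=meso_spec.unit_tag,
    )
    psychro = ActivityTemperatureSeries(
        enzyme_label=psychro_label, rates=tuple(map(float, psychro_rates)), **mk
    )
    meso = ActivityTemperatureSeries(
        enzyme_label=meso_spec.label, rates=tuple(map(float, meso_rates)), **mk
    )
    return psychro, meso


# ---------------------------------------------------------------------------
# Protein fixtures


@dataclass(frozen=True)
class ProteinFixtureSpec:
    """Design of a synthetic protein with planted autolysis sites.

    Candidate K/R sites keep >= ``min_site_separation`` residues between each
    other and the termini so that every cleavage produces gel-resolvable
    (> ~5 kDa) fragments; disulfide pairs are placed within the segments
    between planted labile cuts (a bridge across a cut would make the cut
    invisible on a non-reducing gel). ``n_labile`` of the candidates pass the
    exposure/contact filter; the rest fail by low exposure, a salt bridge or
    a nearby disulfide (chosen at random).
    """

    length: int = 300
    n_candidate_sites: int = 4
    n_labile: int = 1
    n_disulfides: int = 2
    tag: Tag | None = None
    first_residue_number: int = 1
    seed: int = 0
    min_site_separation: int = 50
    exposure_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.length < 30:
            raise ValueError("infeasible fixture: length must be >= 30")
        if not (1 <= self.n_labile <= self.n_candidate_sites):
            raise ValueError("infeasible fixture: need 1 <= n_labile <= n_candidate_sites")


@dataclass(frozen=True)
class ProteinFixture:
    chain: ProteinChain
    disulfides: DisulfideTopology
    exposure: ExposureProfile
    contacts: ContactAnnotation
    triad: tuple[int, ...]
    candidate_sites: tuple[int, ...]
    labile_sites: tuple[int, ...]
    planted_pattern: CleavagePattern


def simulate_protein_fixture(spec: ProteinFixtureSpec) -> ProteinFixture:
    """Generate a protein fixture satisfying the consuming-module invariants."""
    rng = np.random.default_rng(spec.seed)
    sep, L, n = spec.min_site_separation, spec.length, spec.n_candidate_sites
    lo, hi = sep, L - sep
    span = hi - lo - (n - 1) * sep
    if span < 0 or hi < lo:
        raise ValueError("infeasible fixture: more sites than separations allow")
    raw = np.sort(rng.integers(0, span + 1, size=n)) if n else np.array([], int)
    positions = tuple(int(lo + raw[i] + i * sep) for i in range(n))

    labile = tuple(sorted(int(p) for p in rng.choice(positions, spec.n_labile, replace=False)))
    occupied = set(positions)

    # segments between planted labile cuts (cut-after semantics)
    bounds = [0, *labile, L]
    segments = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]

    ss_pairs: list[tuple[int, int]] = []
    for _ in range(spec.n_disulfides):
        for _attempt in range(50):
            seg = segments[int(rng.integers(len(segments)))]
            cands = [p for p in range(seg[0], seg[1] + 1) if p not in occupied]
            if len(cands) < 2:
                continue
            a, b = rng.choice(cands, size=2, replace=False)
            ss_pairs.append((int(min(a, b)), int(max(a, b))))
            occupied.update((int(a), int(b)))
            break

    triad_letters = "HDS"
    free = [p for p in range(1, L + 1) if p not in occupied]
    triad = tuple(sorted(int(p) for p in rng.choice(free, size=3, replace=False)))
    occupied.update(triad)

    seq = list(rng.choice(list(_BACKGROUND_AA), size=L))
    for p in positions:
        seq[p - 1] = str(rng.choice(["K", "R"]))
    for a, b in ss_pairs:
        seq[a - 1] = seq[b - 1] = "C"
    for p, aa in zip(triad, triad_letters):
        seq[p - 1] = aa

    exposure_map: dict[int, float] = {}
    salt: set[int] = set()
    near: set[int] = set()
    for p in positions:
        if p in labile:
            exposure_map[p] = float(rng.uniform(0.35, 0.85))
        else:
            mode = int(rng.integers(3))
            if mode == 0:
                exposure_map[p] = float(rng.uniform(0.02, 0.25))
            elif mode == 1:
                exposure_map[p] = float(rng.uniform(0.35, 0.85))
                salt.add(p)
            else:
                exposure_map[p] = float(rng.uniform(0.35, 0.85))
                near.add(p)

    off = spec.first_residue_number - 1
    shift = lambda t: tuple(x + off for x in t)  # noqa: E731
    chain = ProteinChain(
        sequence="".join(seq),
        first_residue_number=spec.first_residue_number,
        tags=(spec.tag,) if spec.tag else (),
    )
    ss = DisulfideTopology(pairs=tuple((a + off, b + off) for a, b in ss_pairs))
    ss.validate_against(chain)
    exposure = ExposureProfile.from_relative({p + off: v for p, v in exposure_map.items()})
    contacts = ContactAnnotation.from_flags(
        [p + off for p in positions],
        salt_bridged={p + off for p in salt},
        near_disulfide={p + off for p in near},
    )
    return ProteinFixture(
        chain=chain,
        disulfides=ss,
        exposure=exposure,
        contacts=contacts,
        triad=shift(triad),
        candidate_sites=shift(positions),
        labile_sites=shift(labile),
        planted_pattern=CleavagePattern(cut_after=shift(labile)),
    )


def simulate_gel_bands(
    chain: ProteinChain,
    pattern: CleavagePattern,
    ss: DisulfideTopology,
    sigma_kda: float = 0.2,
    seed: int = 0,
    floor_kda: float = 5.0,
    tolerance_kda: float | None = None,
) -> list[BandObservation]:
    """Observed bands for a cleavage pattern: true group masses + noise.

    Groups below ``floor_kda`` are dropped (they migrate out of the gel).
    The per-band tolerance defaults to max(3*sigma, 0.3 kDa), the natural
    acceptance window for a known Gaussian mass error.
    """
    rng = np.random.default_rng(seed)
    tol = tolerance_kda if tolerance_kda is not None else max(3.0 * sigma_kda, 0.3)
    bands: list[BandObservation] = []
    for g in fragment_groups(chain, pattern, ss):
        true_kda = group_mass(g, chain, ss) / 1000.0
        if true_kda < floor_kda:
            continue
        observed = true_kda + float(rng.normal(0.0, sigma_kda)) if sigma_kda > 0 else true_kda
        bands.append(
            BandObservation(
                mass=max(observed, 1e-3),
                tolerance=tol,
                tag_positive=bool(g.retains_tags) if chain.tags else None,
            )
        )
    return bands


# ---------------------------------------------------------------------------
# Geometry fixture: extended peptide builder (backbone + CB)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping point set P onto Q."""
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
    R = Vt.T @ D @ U.T
    return R, Qc - R @ Pc


def _template_sidechain(res_name: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Side-chain heavy atoms from the CCD ideal-geometry residue template,
    rigidly grafted onto a built backbone frame."""
    import biotite.structure.info as struc_info

    tmpl = struc_info.residue(res_name)
    tmpl = tmpl[tmpl.element != "H"]
    names = list(tmpl.atom_name)
    try:
        src = np.array([tmpl.coord[names.index(x)] for x in ("N", "CA", "C")])
    except ValueError:
        return []
    R, t = _kabsch(src, np.array([n, ca, c]))
    out = []
    for name, coord, element in zip(tmpl.atom_name, tmpl.coord, tmpl.element):
        if name in ("N", "CA", "C", "O", "OXT"):
            continue
        out.append((str(name), coord @ R.T + t, str(element)))
    return out


def build_extended_peptide(
    sequence: str, chain_id: str = "A", full_sidechains: bool = True
) -> Structure:
    """An idealized fully extended (phi = psi = 180 deg) peptide.

    Heavy backbone atoms (N, CA, C, O, terminal OXT) are built from internal
    coordinates; side chains are grafted rigidly from CCD ideal-geometry
    residue templates (or truncated at CB with ``full_sidechains=False``).
    This extended conformation is the reference state of the exposure
    normalization, and the builder doubles as a deterministic geometry
    fixture for surface-area tests.
    """
    three = {v: k for k, v in THREE_TO_ONE.items()}
    n_res = len(sequence)
    if n_res == 0:
        raise ValueError("sequence must be non-empty")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = CA + 1.525 * np.array([math.cos(math.radians(69.0)), math.sin(math.radians(69.0)), 0.0])
    backbone = [(N, CA, C)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _place(n_prev, ca_prev, c_prev, 1.329, 117.2, 180.0)  # psi
        ca_next = _place(ca_prev, c_prev, n_next, 1.458, 121.7, 180.0)  # omega
        c_next = _place(c_prev, n_next, ca_next, 1.525, 111.0, 180.0)  # phi
        backbone.append((n_next, ca_next, c_next))

    atoms: list[Atom] = []
    serial = 1

    def add(name: str, pos: np.ndarray, res_name: str, res_seq: int) -> None:
        nonlocal serial
        atoms.append(
            Atom(serial, name, res_name, chain_id, res_seq,
                 float(pos[0]), float(pos[1]), float(pos[2]), name[0])
        )
        serial += 1

    for i, aa in enumerate(sequence):
        res_name = three.get(aa, "UNK")
        n_i, ca_i, c_i = backbone[i]
        add("N", n_i, res_name, i + 1)
        add("CA", ca_i, res_name, i + 1)
        add("C", c_i, res_name, i + 1)
        o_i = _place(n_i, ca_i, c_i, 1.231, 120.5, 0.0)
        add("O", o_i, res_name, i + 1)
        if aa != "G":
            if full_sidechains:
                for name, pos, element in _template_sidechain(res_name, n_i, ca_i, c_i):
                    nonloc = pos  # grafted heavy atom
                    atoms.append(
                        Atom(serial, name, res_name, chain_id, i + 1,
                             float(nonloc[0]), float(nonloc[1]), float(nonloc[2]),
                             element.upper())
                    )
                    serial += 1
            else:
                a_ref = backbone[i - 1][2] if i > 0 else c_i
                tor = 302.6 if i > 0 else 122.6
                cb = _place(a_ref, n_i, ca_i, 1.53, 110.5, tor)
                add("CB", cb, res_name, i + 1)
        if i == n_res - 1:
            oxt = _place(n_i, ca_i, c_i, 1.25, 120.5, 180.0)
            add("OXT", oxt, res_name, i + 1)
    return Structure(atoms=atoms)
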