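"""Logic gates, rewired pathways and feedback loops built from devices.

Devices act on a shared reporter mRNA.  Repressors multiply relative
expression; activators multiply fold-activation; a synergy exponent is
applied when two or more devices are concurrently ligand-engaged, which is
what lets individually weak devices jointly cross the digital threshold
(AND/NAND recipes).  Devices whose antisense domains are mutually
complementary annihilate each other (both inert) whenever both are engaged —
the trick behind the XOR and XNOR recipes.

Networks are small ODE models: per species d[X]/dt = production · (edge
modifiers) − decay · [X], where a connector edge modulates the *translation*
of its target (the protein readout) as a saturating function of its sensor
species; integration is fixed-step RK4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import ConnectorDesign, DesignError
from .regulation import (
    RegulationParams,
    activation_output,
    occupancy,
    repression_output,
)
from .rna_io import packaged_device_params

GATE_TYPES = ("not", "and", "nand", "or", "nor", "xor", "xnor")
DEFAULT_SYNERGY = 2.0
DEFAULT_ANNIHILATION_THRESHOLD = 16  # complementary nt (of 20) for mutual inactivation
ENGAGEMENT_THETA = 0.5  # occupancy above which a gated device counts as engaged

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class GateError(ValueError):
    """A gate recipe cannot be satisfied by the offered device pool."""


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# devices inside circuits


@dataclass(frozen=True)
class DeviceInstance:
    """A designed connector bound to its calibrated regulation parameters."""

    design: ConnectorDesign
    params: RegulationParams
    efficacy_override: Optional[float] = None

    @property
    def mode(self) -> str:
        return "repress" if self.design.topology == "repressor" else "activate"

    @property
    def gated(self) -> bool:
        """Ligand-gated: repressors need the ligand–aptamer roadblock, switch
        activators need the ligand to free their antisense.  Plain activators
        are constitutive."""
        return self.design.topology in ("repressor", "switch_activator")

    @property
    def ligand(self) -> Optional[str]:
        if self.design.topology == "activator":
            return None
        return self.design.aptamers[0].ligand

    @property
    def copies(self) -> int:
        if self.design.topology == "switch_activator":
            return len(self.design.aptamers) - 1  # effector copies
        return len(self.design.aptamers)

    @property
    def efficacy(self) -> float:
        if self.efficacy_override is not None:
            return self.efficacy_override
        if self.design.scores is None:
            raise GateError(f"device {self.design.id} is unscored")
        return self.design.scores.composite


def annihilate(
    d1: ConnectorDesign,
    d2: ConnectorDesign,
    threshold: int = DEFAULT_ANNIHILATION_THRESHOLD,
) -> float:
    """Mutual-sequestration factor between two devices.

    Counts Watson–Crick complementary positions in the antiparallel
    alignment of the two antisense domains; at or above ``threshold``
    complementary positions the devices form a stable duplex and both are
    inert (factor 0), otherwise they do not interact (factor 1)."""
    a1, a2 = d1.antisense, d2.antisense
    n = min(len(a1), len(a2))
    count = sum(1 for i in range(n) if (a1[i], a2[len(a2) - 1 - i]) in _WC)
    return 0.0 if count >= threshold else 1.0


def digitize(analog: float, on_level: float, off_level: float) -> int:
    """1 iff the analog output reaches the midpoint of the calibrated ON and
    OFF reporter levels (ties resolve ON)."""
    if on_level <= off_level:
        raise GateError(f"on_level ({on_level}) must exceed off_level ({off_level})")
    return 1 if analog >= (on_level + off_level) / 2.0 else 0


# ---------------------------------------------------------------------------
# gate construction


@dataclass(frozen=True)
class CircuitSpec:
    """A gate: devices, input ligands with logic-high concentrations, the
    reporter mode, and the calibrated ON/OFF levels used to digitize."""

    gate_type: str
    devices: tuple[DeviceInstance, ...]
    inputs: dict  # ligand -> logic-high concentration (µM)
    input_ligands: tuple[str, ...]  # fixed input order
    reporter_mode: str  # capped | uncapped
    on_level: float
    off_level: float
    synergy: float = DEFAULT_SYNERGY
    annihilation_threshold: int = DEFAULT_ANNIHILATION_THRESHOLD
    target_id: str = ""


@dataclass(frozen=True)
class TruthTable:
    """Input bit tuples → (analog output, digital bit)."""

    input_ligands: tuple[str, ...]
    rows: dict

    def digital(self) -> dict:
        return {bits: bit for bits, (_, bit) in self.rows.items()}

    def to_rows(self) -> list[dict]:
        out = []
        for bits, (analog, bit) in sorted(self.rows.items()):
            row = {lig: b for lig, b in zip(self.input_ligands, bits)}
            row.update({"analog": analog, "output": bit})
            out.append(row)
        return out


def _full_engagement_output(dev: DeviceInstance, high: float) -> float:
    if dev.mode == "repress":
        return repression_output(dev.efficacy, dev.copies, high, dev.params)
    theta = occupancy(high, dev.params) if dev.gated else 1.0
    return activation_output(dev.efficacy, dev.copies, theta, dev.params)


def _logic_high(dev: DeviceInstance, overrides: Optional[dict]) -> float:
    if overrides and dev.ligand in overrides:
        return float(overrides[dev.ligand])
    packaged = packaged_device_params()["logic_high_uM"]
    if dev.ligand in packaged:
        return float(packaged[dev.ligand])
    return 10.0 * dev.params.K  # ~95% occupancy for h around 1.3


def build_gate(
    gate_type: str,
    device_pool: Sequence[DeviceInstance],
    reporter_mode: Optional[str] = None,
    *,
    inputs: Optional[dict] = None,
    ligand: Optional[str] = None,
    synergy: float = DEFAULT_SYNERGY,
    annihilation_threshold: int = DEFAULT_ANNIHILATION_THRESHOLD,
) -> CircuitSpec:
    """Select devices from a ranked pool and assemble a gate.

    Recipes (strong/weak = top/bottom tertile of composite score within the
    needed device mode):

    * NOT — one strong repressor;
    * NOR — two strong repressors, distinct ligands, non-complementary;
    * NAND — two *weak* repressors (singles stay above threshold, the
      engaged pair represses synergistically);
    * OR — two strong ligand-gated activators, non-complementary;
    * AND — two *weak* ligand-gated activators (only the engaged pair
      activates synergistically);
    * XOR — two strong gated activators with mutually complementary
      antisense domains (both inputs → mutual annihilation → low);
    * XNOR — two strong repressors with complementary antisense domains
      (both inputs → annihilation → high).
    """
    g = gate_type.lower()
    if g not in GATE_TYPES:
        raise GateError(f"unknown gate type {gate_type!r}")

    need_mode = "repress" if g in ("not", "nand", "nor", "xnor") else "activate"
    required_reporter = "capped" if need_mode == "repress" else "uncapped"
    if reporter_mode is None:
        reporter_mode = required_reporter
    if reporter_mode != required_reporter:
        raise GateError(
            f"{g.upper()} gate requires the {required_reporter} reporter "
            f"(got {reporter_mode})"
        )

    candidates = [d for d in device_pool if d.mode == need_mode]
    if need_mode == "activate":
        candidates = [d for d in candidates if d.gated]
    if ligand is not None:  # restrict the sensed input (e.g. second NOT gate)
        candidates = [d for d in candidates if d.ligand == ligand]
    if not candidates:
        raise GateError(f"{g.upper()} gate: pool has no {need_mode} devices")
    # strong/weak split at the pool's median composite score
    comps = np.array([d.efficacy for d in candidates])
    median = float(np.quantile(comps, 0.5))
    strong = [d for d in candidates if d.efficacy >= median]
    weak = [d for d in candidates if d.efficacy <= median]
    order = lambda ds: sorted(ds, key=lambda d: (-d.efficacy, d.design.id))

    def pick_pair(pool: list, want_complementary: bool, cls: str) -> tuple:
        # strongest-first for strong recipes, weakest-first for weak ones
        pool = order(pool) if cls == "strong" else order(pool)[::-1]
        for d1, d2 in itertools.combinations(pool, 2):
            if d1.ligand == d2.ligand or d1.ligand is None or d2.ligand is None:
                continue
            comp = annihilate(d1.design, d2.design, annihilation_threshold) == 0.0
            if comp == want_complementary:
                return d1, d2
        kind = "complementary" if want_complementary else "non-complementary"
        raise GateError(
            f"{g.upper()} gate: pool lacks a {kind} pair of {cls} {need_mode} "
            "devices with distinct ligands"
        )

    if g == "not":
        if not strong:
            raise GateError("NOT gate: pool lacks a strong repressor")
        devices = (order(strong)[0],)
    elif g in ("nor",):
        devices = pick_pair(strong, False, "strong")
    elif g == "xnor":
        devices = pick_pair(strong, True, "strong")
    elif g == "nand":
        devices = pick_pair(weak, False, "weak")
    elif g == "or":
        devices = pick_pair(strong, False, "strong")
    elif g == "xor":
        devices = pick_pair(strong, True, "strong")
    else:  # and
        devices = pick_pair(weak, False, "weak")

    highs = {d.ligand: _logic_high(d, inputs) for d in devices}
    input_ligands = tuple(d.ligand for d in devices)
    full = [_full_engagement_output(d, highs[d.ligand]) for d in devices]

    if need_mode == "repress":
        on_level = 1.0
        if g == "nand":
            off_level = float(np.prod(full)) ** synergy
            midpoint = (on_level + off_level) / 2
            for d, e in zip(devices, full):
                if e < midpoint:
                    raise GateError(
                        f"NAND gate: device {d.design.id} represses too "
                        "strongly alone (must be individually weak)"
                    )
        else:
            off_level = max(full)
    else:
        off_level = 1.0
        if g == "and":
            on_level = float(np.prod(full)) ** synergy
            midpoint = (on_level + off_level) / 2
            for d, f in zip(devices, full):
                if f >= midpoint:
                    raise GateError(
                        f"AND gate: device {d.design.id} activates too "
                        "strongly alone (must be individually weak)"
                    )
        else:
            on_level = min(full)
    if on_level <= off_level:
        raise GateError(
            f"{g.upper()} gate: calibrated ON level ({on_level:.3g}) does not "
            f"exceed OFF level ({off_level:.3g})"
        )

    return CircuitSpec(
        gate_type=g,
        devices=tuple(devices),
        inputs=highs,
        input_ligands=input_ligands,
        reporter_mode=reporter_mode,
        on_level=on_level,
        off_level=off_level,
        synergy=synergy,
        annihilation_threshold=annihilation_threshold,
        target_id=devices[0].design.target_id,
    )


def gate_output(spec: CircuitSpec, concentrations: dict) -> float:
    """Analog reporter output for given ligand concentrations (µM)."""
    devs = spec.devices
    theta = []
    for d in devs:
        if d.gated:
            L = float(concentrations.get(d.ligand, 0.0))
            theta.append(occupancy(L, d.params))
        else:
            theta.append(1.0)
    engaged = [t >= ENGAGEMENT_THETA for t in theta]

    annih = [1.0] * len(devs)
    for i, j in itertools.combinations(range(len(devs)), 2):
        if engaged[i] and engaged[j]:
            f = annihilate(devs[i].design, devs[j].design, spec.annihilation_threshold)
            annih[i] *= f
            annih[j] *= f

    e_total, f_total = 1.0, 1.0
    active_rep, active_act = 0, 0
    for d, t, e, a in zip(devs, theta, engaged, annih):
        eff = d.efficacy * a
        if d.mode == "repress":
            L = float(concentrations.get(d.ligand, 0.0))
            e_total *= repression_output(eff, d.copies, L, d.params)
            if e and a > 0 and eff > 0:
                active_rep += 1
        else:
            f_total *= activation_output(eff, d.copies, t, d.params)
            if e and a > 0 and eff > 0:
                active_act += 1
    if active_rep >= 2:
        e_total **= spec.synergy
    if active_act >= 2:
        f_total **= spec.synergy
    return e_total * f_total


def simulate_gate(spec: CircuitSpec) -> TruthTable:
    """Evaluate every input combination and digitize against the calibrated
    ON/OFF midpoint."""
    rows = {}
    n = len(spec.input_ligands)
    for bits in itertools.product((0, 1), repeat=n):
        conc = {
            lig: (spec.inputs[lig] if b else 0.0)
            for lig, b in zip(spec.input_ligands, bits)
        }
        analog = gate_output(spec, conc)
        rows[bits] = (analog, digitize(analog, spec.on_level, spec.off_level))
    return TruthTable(input_ligands=spec.input_ligands, rows=rows)


EXPECTED_TRUTH = {
    "not": {(0,): 1, (1,): 0},
    "and": {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1},
    "nand": {(0, 0): 1, (0, 1): 1, (1, 0): 1, (1, 1): 0},
    "or": {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1},
    "nor": {(0, 0): 1, (0, 1): 0, (1, 0): 0, (1, 1): 0},
    "xor": {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0},
    "xnor": {(0, 0): 1, (0, 1): 0, (1, 0): 0, (1, 1): 1},
}


# ---------------------------------------------------------------------------
# network models


@dataclass(frozen=True)
class SpeciesDef:
    production: float
    decay: float
    init: float = 0.0

    def __post_init__(self):
        if self.production <= 0 or self.decay <= 0:
            raise NetworkError("production and decay rates must be > 0")


@dataclass(frozen=True)
class NetworkEdge:
    """A connector-mediated translational link: ``sensor`` concentration
    modulates the production of ``target`` with the given sign."""

    sensor: str
    target: str
    sign: str  # activate | repress
    params: RegulationParams
    copies: int = 2
    efficacy: float = 1.0

    def __post_init__(self):
        if self.sign not in ("activate", "repress"):
            raise NetworkError(f"edge sign must be activate|repress (got {self.sign})")


@dataclass(frozen=True)
class Perturbation:
    """Timed event: ``set`` replaces the species concentration;
    ``production_scale`` rescales its production rate (knockdown ≪ 1)."""

    time: float
    species: str
    kind: str  # set | production_scale
    value: float


@dataclass(frozen=True)
class NetworkModel:
    species: dict  # name -> SpeciesDef
    edges: tuple

    def __post_init__(self):
        for e in self.edges:
            if e.sensor not in self.species or e.target not in self.species:
                raise NetworkError(
                    f"edge {e.sensor}->{e.target}: undeclared species"
                )


def simulate_network(
    model: NetworkModel,
    t_end: float = 100.0,
    dt: float = 0.01,
    perturbations: Sequence[Perturbation] = (),
) -> dict:
    """Fixed-step RK4 integration of the network.

    Returns ``{"t": array, "<species>": array, ...}``.  Events are applied at
    the first step boundary at or after their time.  Raises on non-finite
    states, reporting the divergence time."""
    if dt <= 0:
        raise NetworkError(f"dt must be > 0 (got {dt})")
    names = list(model.species)
    index = {n: i for i, n in enumerate(names)}
    for p in perturbations:
        if p.species not in index:
            raise NetworkError(f"perturbation on undeclared species {p.species!r}")
        if p.kind not in ("set", "production_scale"):
            raise NetworkError(f"unknown perturbation kind {p.kind!r}")
    prod = np.array([model.species[n].production for n in names], dtype=float)
    decay = np.array([model.species[n].decay for n in names], dtype=float)
    y = np.array([model.species[n].init for n in names], dtype=float)

    def deriv(state: np.ndarray) -> np.ndarray:
        mods = np.ones_like(prod)
        for e in model.edges:
            s = max(float(state[index[e.sensor]]), 0.0)
            if e.sign == "repress":
                m = repression_output(e.efficacy, e.copies, s, e.params)
            else:
                m = activation_output(
                    e.efficacy, e.copies, occupancy(s, e.params), e.params
                )
            mods[index[e.target]] *= m
        return prod * mods - decay * state

    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    traj = np.empty((n_steps + 1, len(names)))
    traj[0] = y
    events = sorted(perturbations, key=lambda p: p.time)
    ev = 0
    for step in range(n_steps):
        t = times[step]
        while ev < len(events) and events[ev].time <= t + 1e-12:
            p = events[ev]
            if p.kind == "set":
                y[index[p.species]] = p.value
            else:
                prod[index[p.species]] *= p.value
            ev += 1
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise NetworkError(f"state diverged (non-finite) at t={times[step + 1]:.4f}")
        traj[step + 1] = y
    out = {"t": times}
    for i, n in enumerate(names):
        out[n] = traj[:, i]
    return out


#: regulation parameters of the packaged OPN–VEGF loop edges: protein sensors
#: operate near the loop's own concentration scale (production/decay = 10).
NETWORK_EDGE_PARAMS = RegulationParams(K=10.0, h=2.0, Emax_r=0.9, Fmax=5.0, kappa=0.5)


def opn_vegf_loop(kind: str, efficacy: float = 0.9) -> NetworkModel:
    """The packaged two-species OPN–VEGF feedback loop.

    In both variants an eIF4G-carrying connector makes OPN an activator of
    VEGF translation; the ``positive`` variant adds the symmetric VEGF→OPN
    activator, the ``negative`` variant instead represses OPN translation in
    response to VEGF."""
    if kind not in ("positive", "negative"):
        raise NetworkError(f"loop kind must be positive|negative (got {kind!r})")
    species = {
        "OPN": SpeciesDef(production=1.0, decay=0.1, init=1.0),
        "VEGF": SpeciesDef(production=1.0, decay=0.1, init=1.0),
    }
    edges = [
        NetworkEdge("OPN", "VEGF", "activate", NETWORK_EDGE_PARAMS, efficacy=efficacy),
        NetworkEdge(
            "VEGF",
            "OPN",
            "activate" if kind == "positive" else "repress",
            NETWORK_EDGE_PARAMS,
            efficacy=efficacy,
        ),
    ]
    return NetworkModel(species=species, edges=tuple(edges))


# ---------------------------------------------------------------------------
# application scenarios


def rewire_scenario(
    tf_level: float,
    connector: DeviceInstance,
    *,
    transcription_gain: float = 2.0,
    tf_K: float = 1.0,
    baseline: float = 1.0,
) -> tuple[float, float]:
    """Pathway rewiring: a transcription factor still *transcribes* its
    downstream gene, but a connector sensing the same factor represses its
    *translation*.

    Returns (mRNA readout, protein readout): the mRNA arm rises with
    ``tf_level`` untouched by the connector; the protein readout is the mRNA
    level times the connector's repression output driven by the same
    factor."""
    if connector.design.topology != "repressor":
        raise DesignError("rewire_scenario needs a repressor connector")
    if tf_level < 0:
        raise NetworkError(f"tf_level must be >= 0 (got {tf_level})")
    mrna = baseline * (1.0 + transcription_gain * tf_level / (tf_K + tf_level))
    protein = mrna * repression_output(
        connector.efficacy, connector.copies, tf_level, connector.params
    )
    return mrna, protein


def and_classifier(
    promoter_active: bool,
    ligand_present: bool,
    device: DeviceInstance,
    *,
    logic_high: Optional[float] = None,
) -> float:
    """Tumor-targeting AND gate: a cancer-selective promoter drives a
    ribozyme-flanked repressor, and the ligand arms it.

    Returns the survival-gene knockdown level: positive only when the
    promoter is active AND the ligand is present, zero otherwise."""
    if not device.design.ribozyme_flanked or device.design.topology != "repressor":
        raise DesignError(
            "and_classifier needs a ribozyme-flanked repressor device"
        )
    if not promoter_active:
        return 0.0
    high = logic_high if logic_high is not None else _logic_high(device, None)
    L = high if ligand_present else 0.0
    return 1.0 - repression_output(device.efficacy, device.copies, L, device.params)


def redirect_scenario(
    sensor_level: float,
    activators: Sequence[DeviceInstance],
    repressors: Sequence[DeviceInstance],
    *,
    baseline: float = 1.0,
) -> dict:
    """Simultaneous ON/OFF redirection of an oncogenic signal.

    Two sequestration-switch activators turn the sensed signal into
    activation of their targets (tumor suppressors) while two repressors
    carrying the same sensor aptamer suppress theirs (oncogenes).  Returns
    ``{target_id: output level}`` relative to ``baseline``."""
    if len(activators) != 2 or len(repressors) != 2:
        raise DesignError("redirect_scenario expects 2 activators and 2 repressors")
    for a in activators:
        if a.design.topology != "switch_activator":
            raise DesignError(
                f"activator {a.design.id} must be a switch_activator"
            )
    for r in repressors:
        if r.design.topology != "repressor":
            raise DesignError(f"repressor {r.design.id} must be a repressor")
    out = {}
    for a in activators:
        theta = occupancy(sensor_level, a.params)
        out[a.design.target_id] = baseline * activation_output(
            a.efficacy, a.copies, theta, a.params
        )
    for r in repressors:
        out[r.design.target_id] = baseline * repression_output(
            r.efficacy, r.copies, sensor_level, r.params
        )
    return out
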