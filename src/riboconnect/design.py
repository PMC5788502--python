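"""Design of trans-acting signal-connector devices.

A signal-connector is a chimeric RNA made of a 20-nt antisense domain that
recognizes a window on the target mRNA plus one or more aptamer domains.
Three topologies are supported:

* **repressor** — antisense + sensor-aptamer copies; the ligand–aptamer
  complex acts as a roadblock to ribosome scanning/elongation;
* **activator** — antisense + eIF4G-effector-aptamer copies; recruitment of
  initiation machinery enhances translation constitutively;
* **switch_activator** — sensor aptamer + antisense + effector copies, with
  the antisense complementary to the sensor stem: the device is sequestered
  (inert) until ligand binding stabilizes the aptamer and frees the
  antisense.

Candidate designs are folded and selected on two structural criteria — the
antisense domain must stay exposed (single-stranded) and each aptamer must
retain its reference stem — and ranked with a 5ʹ-distance efficacy prior,
since devices targeting close to the 5ʹ cap repress/activate more strongly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .fold import fold, pair_partner_map
from .rna_io import Aptamer, AptamerLibrary, Transcript, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_ANTISENSE_LENGTH = 20
DEFAULT_LINKER = "AAA"  # unpaired spacer between modules
DEFAULT_LAMBDA = 300.0  # nt, decay length of the 5'-distance efficacy prior
DEFAULT_TAU_EXPOSED = 0.8
DEFAULT_TAU_PRESERVED = 0.8
ALLOWED_COPIES = (1, 2, 3)

TOPOLOGIES = ("repressor", "activator", "switch_activator")


class DesignError(ValueError):
    """Raised when a device cannot be assembled or scored as requested."""


@dataclass(frozen=True)
class ModulePlacement:
    """Where one module sits inside the assembled chimera (half-open)."""

    kind: str  # "antisense" or an aptamer id
    start: int
    end: int


@dataclass(frozen=True)
class StructureScore:
    """Structural selection scores of one design.

    exposedness — fraction of antisense nucleotides unpaired in the folded
    chimera; preservation — fraction of aptamer reference pairs reproduced
    (averaged over copies); position_prior — 5ʹ-distance efficacy prior;
    composite — their product; passed — both structural thresholds met.
    """

    exposedness: float
    preservation: float
    position_prior: float
    composite: float
    passed: bool


@dataclass(frozen=True)
class SwitchState:
    """Two-state evaluation of a sequestration switch.

    off_score — stability of the sequestered conformation; on_score —
    stability of the aptamer-formed conformation plus the ligand binding
    bonus; state — "OFF" or "ON" given the queried ligand presence.
    """

    off_score: float
    on_score: float
    state: str


@dataclass(frozen=True)
class ConnectorDesign:
    """An assembled signal-connector chimera."""

    id: str
    topology: str
    target_id: str
    window: tuple[int, int]
    region: str
    antisense: str
    modules: tuple[ModulePlacement, ...]
    linker: str
    full_sequence: str
    aptamers: tuple[Aptamer, ...]  # aptamer object per aptamer module, in order
    scores: Optional[StructureScore] = None
    ribozyme_flanked: bool = False
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise DesignError(f"unknown topology {self.topology!r}")

    @property
    def antisense_span(self) -> tuple[int, int]:
        for m in self.modules:
            if m.kind == "antisense":
                return (m.start, m.end)
        raise DesignError(f"design {self.id} has no antisense module")

    def module_summary(self) -> list[tuple[str, int]]:
        """(module kind, copies) in first-appearance order."""
        out: list[tuple[str, int]] = []
        for m in self.modules:
            if out and out[-1][0] == m.kind:
                out[-1] = (m.kind, out[-1][1] + 1)
            else:
                out.append((m.kind, 1))
        return out


# ---------------------------------------------------------------------------
# window enumeration and assembly


def enumerate_windows(
    transcript: Transcript,
    region: str = "both",
    length: int = DEFAULT_ANTISENSE_LENGTH,
    step: int = 1,
) -> list[tuple[int, int]]:
    """All half-open target windows of ``length`` fully inside the requested
    region(s), ascending by start.  Returns an empty list (with a warning)
    when the region is shorter than the window."""
    if step < 1:
        raise DesignError(f"step must be >= 1 (got {step})")
    spans = []
    reg = region.lower()
    if reg in ("utr5", "both"):
        spans.append(transcript.utr5)
    if reg in ("cds", "both"):
        spans.append(transcript.cds)
    if not spans:
        raise DesignError(f"region must be utr5|cds|both (got {region!r})")
    windows = []
    for lo, hi in spans:
        if hi - lo < length:
            logger.warning(
                "transcript %s: region [%d,%d) shorter than window length %d",
                transcript.id, lo, hi, length,
            )
            continue
        windows.extend((s, s + length) for s in range(lo, hi - length + 1, step))
    return sorted(windows)


def antisense_for_window(transcript: Transcript, window: tuple[int, int]) -> str:
    """Reverse complement of the target window (the antisense domain)."""
    s, e = window
    if not (0 <= s < e <= len(transcript.sequence)):
        raise DesignError(f"window {window} outside transcript {transcript.id}")
    return reverse_complement(transcript.sequence[s:e])


def _check_copies(copies: int) -> None:
    if copies not in ALLOWED_COPIES:
        raise DesignError(f"copies must be one of {ALLOWED_COPIES} (got {copies})")


def _region_of(transcript: Optional[Transcript], window: tuple[int, int]) -> str:
    if transcript is None:
        return "UTR5"
    return "UTR5" if window[1] <= transcript.utr5_end else "CDS"


def _assemble(
    parts: Sequence[tuple[str, str]], linker: str
) -> tuple[str, tuple[ModulePlacement, ...]]:
    """Concatenate (kind, sequence) parts with linkers; return sequence and
    module placements (linkers are not modules)."""
    chunks: list[str] = []
    placements: list[ModulePlacement] = []
    pos = 0
    for idx, (kind, seq) in enumerate(parts):
        if idx > 0:
            chunks.append(linker)
            pos += len(linker)
        chunks.append(seq)
        placements.append(ModulePlacement(kind, pos, pos + len(seq)))
        pos += len(seq)
    return "".join(chunks), tuple(placements)


def assemble_repressor(
    antisense: str,
    sensor: Aptamer,
    copies: int = 2,
    linker: str = DEFAULT_LINKER,
    *,
    id: Optional[str] = None,
    target_id: str = "",
    window: Optional[tuple[int, int]] = None,
    region: str = "UTR5",
    ribozyme_flanked: bool = False,
) -> ConnectorDesign:
    """Antisense + ``copies`` sensor-aptamer copies: a roadblock repressor."""
    _check_copies(copies)
    antisense = reverse_complement(reverse_complement(antisense))  # normalize
    parts = [("antisense", antisense)] + [(sensor.id, sensor.sequence)] * copies
    full, modules = _assemble(parts, linker)
    return ConnectorDesign(
        id=id or f"rep_{sensor.id}{copies}x_{target_id}_{(window or (0, 0))[0]}",
        topology="repressor",
        target_id=target_id,
        window=window or (0, len(antisense)),
        region=region,
        antisense=antisense,
        modules=modules,
        linker=linker,
        full_sequence=full,
        aptamers=(sensor,) * copies,
        ribozyme_flanked=ribozyme_flanked,
    )


def assemble_activator(
    antisense: str,
    effector: Aptamer,
    copies: int = 2,
    linker: str = DEFAULT_LINKER,
    *,
    id: Optional[str] = None,
    target_id: str = "",
    window: Optional[tuple[int, int]] = None,
    region: str = "UTR5",
) -> ConnectorDesign:
    """Antisense + eIF4G-effector copies: a constitutive activator.

    Single-copy devices are flagged ``reduced-efficacy``: removing one of
    the two effector copies collapses the induced activation.
    """
    _check_copies(copies)
    if effector.role != "effector":
        raise DesignError(
            f"aptamer {effector.id} has role {effector.role!r}; an activator "
            "needs an effector (eIF4G-recruiting) aptamer"
        )
    antisense = reverse_complement(reverse_complement(antisense))
    parts = [("antisense", antisense)] + [(effector.id, effector.sequence)] * copies
    full, modules = _assemble(parts, linker)
    notes = ("reduced-efficacy",) if copies == 1 else ()
    return ConnectorDesign(
        id=id or f"act_{effector.id}{copies}x_{target_id}_{(window or (0, 0))[0]}",
        topology="activator",
        target_id=target_id,
        window=window or (0, len(antisense)),
        region=region,
        antisense=antisense,
        modules=modules,
        linker=linker,
        full_sequence=full,
        aptamers=(effector,) * copies,
        notes=notes,
    )


def assemble_switch_activator(
    sensor: Aptamer,
    antisense: str,
    effector: Aptamer,
    copies: int = 2,
    linker: str = DEFAULT_LINKER,
    *,
    id: Optional[str] = None,
    target_id: str = "",
    window: Optional[tuple[int, int]] = None,
    region: str = "UTR5",
    verify_off_state: bool = True,
) -> ConnectorDesign:
    """Sensor aptamer + antisense + effector copies: a sequestration switch.

    The antisense must contain the perfect reverse complement of the sensor
    stem so the stem can sequester it in the ligand-free state; mismatches
    are a hard error listing their positions.
    """
    _check_copies(copies)
    if effector.role != "effector":
        raise DesignError(
            f"aptamer {effector.id} has role {effector.role!r}; expected effector"
        )
    if sensor.role != "sensor":
        raise DesignError(f"aptamer {sensor.id} has role {sensor.role!r}; expected sensor")
    antisense = reverse_complement(reverse_complement(antisense))
    _check_stem_complementarity(antisense, sensor)

    parts = (
        [(sensor.id, sensor.sequence), ("antisense", antisense)]
        + [(effector.id, effector.sequence)] * copies
    )
    full, modules = _assemble(parts, linker)
    design = ConnectorDesign(
        id=id or f"sw_{sensor.id}_{effector.id}{copies}x_{target_id}",
        topology="switch_activator",
        target_id=target_id,
        window=window or (0, len(antisense)),
        region=region,
        antisense=antisense,
        modules=modules,
        linker=linker,
        full_sequence=full,
        aptamers=(sensor,) + (effector,) * copies,
    )
    if verify_off_state:
        state = evaluate_switch(design, ligand_present=False)
        if state.state != "OFF":
            raise DesignError(
                f"switch {design.id}: sequestered conformation is not favored "
                f"without ligand (off={state.off_score}, on={state.on_score})"
            )
    return design


def _check_stem_complementarity(antisense: str, sensor: Aptamer) -> None:
    """The antisense must contain a perfect reverse complement of the sensor
    stem; report the best ungapped alignment's mismatches otherwise."""
    stem_rc = reverse_complement(sensor.stem_sequence)
    L = len(stem_rc)
    if len(antisense) < L:
        raise DesignError(
            f"antisense ({len(antisense)} nt) shorter than sensor stem ({L} nt)"
        )
    best_mismatches: Optional[list[int]] = None
    for off in range(len(antisense) - L + 1):
        mism = [i for i in range(L) if antisense[off + i] != stem_rc[i]]
        if best_mismatches is None or len(mism) < len(best_mismatches):
            best_mismatches = mism
        if not mism:
            return
    raise DesignError(
        f"antisense is not complementary to the {sensor.id} stem: best "
        f"alignment has {len(best_mismatches)} mismatches at stem positions "
        f"{best_mismatches}"
    )


# ---------------------------------------------------------------------------
# scoring and ranking


def position_prior(
    window_start: int, transcript: Transcript, lam: float = DEFAULT_LAMBDA
) -> float:
    """5ʹ-distance efficacy prior exp(−start/λ).

    Repression and activation are both stronger close to the 5ʹ end of the
    mRNA; the strictly decreasing exponential (1.0 at the cap, e⁻¹ at λ)
    encodes that inverse correlation.
    """
    if not (0 <= window_start <= len(transcript.sequence)):
        raise DesignError(
            f"window start {window_start} outside transcript {transcript.id}"
        )
    if lam <= 0:
        raise DesignError(f"lambda must be > 0 (got {lam})")
    return math.exp(-window_start / lam)


def score_design(
    design: ConnectorDesign,
    target: Transcript,
    library: AptamerLibrary,
    *,
    lam: float = DEFAULT_LAMBDA,
    tau_exposed: float = DEFAULT_TAU_EXPOSED,
    tau_preserved: float = DEFAULT_TAU_PRESERVED,
) -> ConnectorDesign:
    """Fold the chimera and score it; returns a copy with scores attached.

    Exposedness and preservation are measured on the ligand-free fold for
    repressors/activators; for sequestration switches the deterministic
    tie-break of the fold engine yields the aptamer-formed (ON-state)
    conformation, which is the state in which the antisense must be usable.
    """
    s, e = design.window
    if design.antisense != reverse_complement(target.sequence[s:e]):
        raise DesignError(
            f"design {design.id}: antisense is not the reverse complement of "
            f"target window {design.window}"
        )
    structure = fold(design.full_sequence)
    a_start, a_end = design.antisense_span
    partner = pair_partner_map(structure, len(design.full_sequence))
    unpaired = sum(1 for i in range(a_start, a_end) if partner[i] is None)
    exposedness = unpaired / (a_end - a_start)

    apt_modules = [m for m in design.modules if m.kind != "antisense"]
    if len(apt_modules) != len(design.aptamers):
        raise DesignError(f"design {design.id}: module/aptamer bookkeeping mismatch")
    fractions = []
    for placement, aptamer in zip(apt_modules, design.aptamers):
        if aptamer.id not in library:
            raise DesignError(
                f"design {design.id}: aptamer {aptamer.id} missing from library"
            )
        ref_pairs = library[aptamer.id].reference_pairs
        if not ref_pairs:
            raise DesignError(f"aptamer {aptamer.id}: empty reference structure")
        shifted = {(i + placement.start, j + placement.start) for i, j in ref_pairs}
        kept = len(shifted & structure.pairs)
        fractions.append(kept / len(ref_pairs))
    preservation = sum(fractions) / len(fractions)

    prior = position_prior(design.window[0], target, lam)
    composite = exposedness * preservation * prior
    passed = exposedness >= tau_exposed and preservation >= tau_preserved
    score = StructureScore(
        exposedness=exposedness,
        preservation=preservation,
        position_prior=prior,
        composite=composite,
        passed=passed,
    )
    return replace(design, scores=score)


def rank_designs(
    designs: Iterable[ConnectorDesign],
    thresholds: tuple[float, float] = (DEFAULT_TAU_EXPOSED, DEFAULT_TAU_PRESERVED),
) -> list[ConnectorDesign]:
    """Drop designs failing the structural thresholds; sort the rest by
    composite score descending (ties: smaller window start, then id)."""
    tau_e, tau_p = thresholds
    kept = []
    for d in designs:
        if d.scores is None:
            raise DesignError(f"design {d.id} is unscored")
        if d.scores.exposedness >= tau_e and d.scores.preservation >= tau_p:
            kept.append(d)
    return sorted(kept, key=lambda d: (-d.scores.composite, d.window[0], d.id))


# ---------------------------------------------------------------------------
# sequestration switch evaluation


def evaluate_switch(design: ConnectorDesign, ligand_present: bool) -> SwitchState:
    """Two-state evaluation of a sequestration switch.

    OFF conformation: the sensor stem cannot close internally (its 3ʹ strand
    is held unpaired), so the 5ʹ stem strand pairs the antisense — the
    sequestered state.  ON conformation: the antisense is held unpaired and
    the sensor folds its reference stem.  Ligand binding adds the sensor's
    ``binding_bonus`` to the ON side; the device is ON iff the effective ON
    score strictly exceeds the OFF score (ties stay OFF).
    """
    if design.topology != "switch_activator":
        raise DesignError(
            f"evaluate_switch requires a switch_activator (got {design.topology})"
        )
    sensor = design.aptamers[0]
    sensor_mod = design.modules[0]
    # absolute indices of the stem's 3' partner strand inside the chimera
    ref_partner = {}
    for i, j in sensor.reference_pairs:
        ref_partner[i] = j
        ref_partner[j] = i
    partner_half = sorted(
        {ref_partner[i] for i in range(*sensor.stem) if i in ref_partner}
    )
    if not partner_half:
        raise DesignError(f"sensor {sensor.id}: stem has no reference pairs")
    partner_abs = {sensor_mod.start + j for j in partner_half}
    a_start, a_end = design.antisense_span
    antisense_abs = set(range(a_start, a_end))

    off_score = fold(design.full_sequence, constraints=partner_abs).score
    on_base = fold(design.full_sequence, constraints=antisense_abs).score
    on_score = on_base + sensor.binding_bonus

    effective_on = on_score if ligand_present else on_score - sensor.binding_bonus
    state = "ON" if effective_on > off_score else "OFF"
    return SwitchState(off_score=float(off_score), on_score=float(on_score), state=state)


# ---------------------------------------------------------------------------
# pipeline convenience


def design_connectors(
    target: Transcript,
    library: AptamerLibrary,
    topology: str,
    *,
    sensor_id: Optional[str] = None,
    effector_id: Optional[str] = None,
    region: str = "both",
    length: int = DEFAULT_ANTISENSE_LENGTH,
    step: int = 1,
    copies: int = 2,
    linker: str = DEFAULT_LINKER,
    lam: float = DEFAULT_LAMBDA,
    thresholds: tuple[float, float] = (DEFAULT_TAU_EXPOSED, DEFAULT_TAU_PRESERVED),
) -> list[ConnectorDesign]:
    """Enumerate windows, assemble, score and rank devices for one target."""
    if topology == "repressor":
        if sensor_id is None:
            raise DesignError("repressor design needs --sensor")
        sensor = library[sensor_id]
    elif topology == "activator":
        if effector_id is None:
            raise DesignError("activator design needs --effector")
        effector = library[effector_id]
    else:
        raise DesignError(
            "design_connectors assembles repressor|activator devices; build "
            "switch_activator devices explicitly via assemble_switch_activator"
        )

    designs = []
    for window in enumerate_windows(target, region, length, step):
        anti = antisense_for_window(target, window)
        reg = _region_of(target, window)
        if topology == "repressor":
            d = assemble_repressor(
                anti, sensor, copies, linker,
                target_id=target.id, window=window, region=reg,
            )
        else:
            d = assemble_activator(
                anti, effector, copies, linker,
                target_id=target.id, window=window, region=reg,
            )
        designs.append(
            score_design(
                d, target, library,
                lam=lam, tau_exposed=thresholds[0], tau_preserved=thresholds[1],
            )
        )
    return rank_designs(designs, thresholds)
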