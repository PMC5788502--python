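"""Seeded demo assemblies: device pools and scenario devices.

Everything here is derived from the synthetic fixture generator plus the
packaged aptamer library and device calibrations, so gates, loops and the
classifier can be simulated end-to-end from a single seed without external
data.  Strong devices target windows near the 5ʹ cap (high position prior),
weak devices target windows deep in the CDS; the fixture transcript's
embedded inverted repeat provides the mutually complementary antisense pair
needed by the XOR/XNOR recipes.
"""

from __future__ import annotations

from .circuits import DeviceInstance
from .design import (
    antisense_for_window,
    assemble_repressor,
    assemble_switch_activator,
    score_design,
)
from .fixtures import (
    FixtureSpec,
    generate_fixture_transcript,
    inverted_repeat_windows,
    sensor_for_antisense,
)
from .regulation import RegulationParams
from .rna_io import AptamerLibrary, Transcript, packaged_aptamer_library, packaged_device_params

#: CDS starts scanned for structurally passing "weak" target windows.
_WEAK_START_SCAN = range(420, 561, 10)


def device_params(name: str) -> RegulationParams:
    """RegulationParams for one packaged device calibration entry."""
    d = packaged_device_params()["devices"][name]
    return RegulationParams(
        K=d["K"], h=d["h"], Emax_r=d["Emax_r"], Fmax=d["Fmax"], kappa=d["kappa"]
    )


def _region_of(target: Transcript, window: tuple[int, int]) -> str:
    return "UTR5" if window[1] <= target.utr5_end else "CDS"


def _make_repressor(
    target: Transcript,
    window: tuple[int, int],
    sensor_id: str,
    params: RegulationParams,
    lib: AptamerLibrary,
    dev_id: str,
    *,
    ribozyme_flanked: bool = False,
) -> DeviceInstance:
    anti = antisense_for_window(target, window)
    d = assemble_repressor(
        anti, lib[sensor_id], 2,
        id=dev_id, target_id=target.id, window=window,
        region=_region_of(target, window), ribozyme_flanked=ribozyme_flanked,
    )
    return DeviceInstance(score_design(d, target, lib), params)


def _make_switch(
    target: Transcript,
    window: tuple[int, int],
    ligand: str,
    params: RegulationParams,
    lib: AptamerLibrary,
    dev_id: str,
    *,
    binding_bonus: float = 5.0,
) -> DeviceInstance:
    anti = antisense_for_window(target, window)
    sensor = sensor_for_antisense(
        anti, id=f"{dev_id}_sensor", ligand=ligand, binding_bonus=binding_bonus
    )
    lib.add(sensor)
    d = assemble_switch_activator(
        sensor, anti, lib["eif4g"], 2,
        id=dev_id, target_id=target.id, window=window,
        region=_region_of(target, window),
    )
    return DeviceInstance(score_design(d, target, lib), params)


def _passing_weak_windows(make, n: int = 2) -> list[tuple[int, int]]:
    """First ``n`` CDS windows (scanned 5ʹ→3ʹ) whose device passes the
    structural thresholds."""
    found = []
    for start in _WEAK_START_SCAN:
        window = (start, start + 20)
        try:
            dev = make(window)
        except Exception:
            continue
        if dev.design.scores.passed:
            found.append(window)
        if len(found) == n:
            return found
    raise RuntimeError("fixture transcript yielded too few passing weak windows")


def demo_gate_pool(seed: int = 0) -> dict:
    """Device pool covering all seven gate recipes.

    Returns ``{"devices": [...], "capped": Transcript, "uncapped":
    Transcript, "library": AptamerLibrary}``.  Repressors act on the capped
    reporter; ligand-gated (switch) activators act on the uncapped one.
    """
    spec = FixtureSpec(seed=seed)
    capped = generate_fixture_transcript(spec, id="reporter_capped", capped=True)
    uncapped = generate_fixture_transcript(spec, id="reporter_uncapped", capped=False)
    lib = packaged_aptamer_library()
    w1, w2 = inverted_repeat_windows(spec)
    w3 = (25, 45)  # strong, non-complementary to w1/w2

    p_theo = device_params("theophylline_repressor_2x")
    p_tet = device_params("tetracycline_repressor_2x")
    p_theo_sw = device_params("theophylline_eif4g_switch_2x")
    p_tet_sw = device_params("tetracycline_eif4g_switch_2x")

    devices = [
        _make_repressor(capped, w1, "theo", p_theo, lib, "R_theo_strong"),
        _make_repressor(capped, w2, "tet", p_tet, lib, "R_tet_comp"),
        _make_repressor(capped, w3, "tet", p_tet, lib, "R_tet_strong"),
    ]
    weak_rep = _passing_weak_windows(
        lambda w: _make_repressor(capped, w, "theo", p_theo, lib, f"probe_{w[0]}")
    )
    devices.append(
        _make_repressor(capped, weak_rep[0], "theo", p_theo, lib, "R_theo_weak")
    )
    devices.append(
        _make_repressor(capped, weak_rep[1], "tet", p_tet, lib, "R_tet_weak")
    )

    devices.append(
        _make_switch(uncapped, w1, "theophylline", p_theo_sw, lib, "A_theo_strong")
    )
    devices.append(
        _make_switch(uncapped, w2, "tetracycline", p_tet_sw, lib, "A_tet_comp")
    )
    devices.append(
        _make_switch(uncapped, w3, "tetracycline", p_tet_sw, lib, "A_tet_strong")
    )
    probe_lib = packaged_aptamer_library()
    weak_act = _passing_weak_windows(
        lambda w: _make_switch(
            uncapped, w, "theophylline", p_theo_sw, probe_lib, f"probe_sw_{w[0]}"
        )
    )
    devices.append(
        _make_switch(uncapped, weak_act[0], "theophylline", p_theo_sw, lib, "A_theo_weak")
    )
    devices.append(
        _make_switch(uncapped, weak_act[1], "tetracycline", p_tet_sw, lib, "A_tet_weak")
    )

    return {"devices": devices, "capped": capped, "uncapped": uncapped, "library": lib}


def demo_rewire_connector(seed: int = 0) -> DeviceInstance:
    """Repressor sensing β-catenin, targeting the 5ʹ-UTR of a synthetic
    c-Myc stand-in transcript (pathway rewiring scenario)."""
    spec = FixtureSpec(seed=seed + 11)
    target = generate_fixture_transcript(spec, id="cMyc_synthetic")
    lib = packaged_aptamer_library()
    return _make_repressor(
        target, (0, 20), "bcat",
        device_params("protein_sensor_repressor_2x"), lib, "R_bcat_cMyc",
    )


def demo_classifier_device(seed: int = 0) -> DeviceInstance:
    """Ribozyme-flanked theophylline repressor against a synthetic survival
    gene (tumor-targeting AND-gate classifier)."""
    spec = FixtureSpec(seed=seed + 12)
    target = generate_fixture_transcript(spec, id="survival_synthetic")
    lib = packaged_aptamer_library()
    return _make_repressor(
        target, (0, 20), "theo",
        device_params("theophylline_repressor_2x"), lib, "R_theo_survival",
        ribozyme_flanked=True,
    )


def demo_redirect_devices(
    seed: int = 0,
) -> tuple[list[DeviceInstance], list[DeviceInstance]]:
    """Devices of the simultaneous ON/OFF redirection scenario.

    Two NF-kB-gated switch activators target synthetic Bax and p21
    transcripts; two repressors carrying NF-kB sensor aptamers target
    synthetic Bcl2 and c-Myc transcripts."""
    p_act = device_params("protein_sensor_activator_2x")
    p_rep = device_params("protein_sensor_repressor_2x")
    activators, repressors = [], []
    for k, gene in enumerate(("Bax", "p21")):
        spec = FixtureSpec(seed=seed + 20 + k)
        target = generate_fixture_transcript(spec, id=f"{gene}_synthetic")
        lib = packaged_aptamer_library()
        activators.append(
            _make_switch(
                target, (0, 20), "NF-kB", p_act, lib, f"A_nfkb_{gene}",
                binding_bonus=7.0,
            )
        )
    for k, gene in enumerate(("Bcl2", "cMyc")):
        spec = FixtureSpec(seed=seed + 30 + k)
        target = generate_fixture_transcript(spec, id=f"{gene}_synthetic")
        lib = packaged_aptamer_library()
        repressors.append(
            _make_repressor(
                target, (0, 20), "nfkb", p_rep, lib, f"R_nfkb_{gene}",
            )
        )
    return activators, repressors
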