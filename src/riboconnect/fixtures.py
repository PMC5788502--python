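"""Deterministic synthetic fixtures: toy transcripts, hairpin aptamers and a
demo device pool.

No deposited target or device sequences exist for this system, so every test
and demo input is generated here from a seed.  A fixture transcript is a
pseudo-random mRNA with an annotated 5ʹ-UTR/CDS boundary; it always embeds a
20-nt inverted-repeat pair (one copy at the start of the 5ʹ-UTR, its reverse
complement at the start of the CDS) so that devices targeting the two copies
have mutually complementary antisense domains — the design trick behind the
XOR/XNOR gates.  Toy aptamers are perfect stem–loops.  All randomness flows
through ``FixtureSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rna_io import (
    Aptamer,
    AptamerLibrary,
    Transcript,
    packaged_aptamer_library,
    reverse_complement,
)

#: 5' copy of the embedded inverted repeat (all-C, so one derived antisense
#: is purine-only and the other pyrimidine-only; both leave aptamer hairpins
#: intact in the chimera fold).
INVERTED_REPEAT = "C" * 20
REPEAT_LENGTH = len(INVERTED_REPEAT)

#: additional device-accessible windows embedded into fixture transcripts,
#: emulating accessible (unstructured) target sites.  Pyrimidine-only
#: content makes the derived antisense purine-only, which cannot unzip the
#: packaged aptamer stems; the U patterns keep every pair of derived
#: antisense domains below the mutual-annihilation complementarity
#: threshold.  Keys are window start positions.
ACCESS_WINDOW_STRONG = "CUCCUCCUCCUCCUCCUCCU"  # near the 5' end (start 25)
ACCESS_WINDOW_WEAK_1 = "CCUCUCCUCCUCCUCUCCUC"  # deep in the CDS (start 440)
ACCESS_WINDOW_WEAK_2 = "UCCUCCUCUCCUCUCCUCCC"  # deep in the CDS (start 480)
ACCESS_WINDOW_STARTS = {"strong": 25, "weak1": 440, "weak2": 480}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic fixture generator."""

    seed: int = 0
    transcript_length: int = 600
    utr5_length: int = 60
    gc_content: float = 0.5
    aptamer_stem_length: int = 7
    aptamer_loop_length: int = 4
    embed_inverted_repeat: bool = True

    def __post_init__(self):
        if self.transcript_length <= 0 or self.utr5_length <= 0:
            raise FixtureError("lengths must be positive")
        if self.utr5_length >= self.transcript_length:
            raise FixtureError("utr5_length must be < transcript_length")
        if not (0 <= self.gc_content <= 1):
            raise FixtureError("gc_content must be in [0, 1]")
        if self.aptamer_stem_length < 3 or self.aptamer_loop_length < 3:
            raise FixtureError("aptamer stem and loop must each be >= 3 nt")


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = []
    for _ in range(length):
        if rng.random() < gc:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "U")
    return "".join(bases)


def inverted_repeat_windows(spec: FixtureSpec) -> tuple[tuple[int, int], tuple[int, int]]:
    """Deterministic windows of the embedded inverted repeat: the 5ʹ copy at
    the start of the UTR, the reverse-complement copy at the start of the CDS."""
    w1 = (0, REPEAT_LENGTH)
    w2 = (spec.utr5_length, spec.utr5_length + REPEAT_LENGTH)
    return w1, w2


def generate_fixture_transcript(
    spec: FixtureSpec, *, id: str = "toy_mrna", capped: bool = True
) -> Transcript:
    """Reproducible pseudo-random transcript with the requested composition.

    Same seed → identical output.  When ``embed_inverted_repeat`` is set (and
    both regions are long enough) the fixed 20-nt repeat and its reverse
    complement overwrite the window positions given by
    :func:`inverted_repeat_windows`.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_rna(rng, spec.transcript_length, spec.gc_content))
    if (
        spec.embed_inverted_repeat
        and spec.utr5_length >= REPEAT_LENGTH
        and spec.transcript_length - spec.utr5_length >= REPEAT_LENGTH
    ):
        (s1, e1), (s2, e2) = inverted_repeat_windows(spec)
        seq[s1:e1] = INVERTED_REPEAT
        seq[s2:e2] = reverse_complement(INVERTED_REPEAT)
        for content, start in (
            (ACCESS_WINDOW_STRONG, ACCESS_WINDOW_STARTS["strong"]),
            (ACCESS_WINDOW_WEAK_1, ACCESS_WINDOW_STARTS["weak1"]),
            (ACCESS_WINDOW_WEAK_2, ACCESS_WINDOW_STARTS["weak2"]),
        ):
            end = start + len(content)
            if start == ACCESS_WINDOW_STARTS["strong"]:
                if end <= spec.utr5_length:
                    seq[start:end] = content
            elif spec.utr5_length <= start and end <= spec.transcript_length:
                seq[start:end] = content
    return Transcript(
        id=id,
        sequence="".join(seq),
        utr5_end=spec.utr5_length,
        cds_end=spec.transcript_length,
        capped=capped,
    )


def generate_toy_aptamer(
    spec: FixtureSpec,
    *,
    id: str = "toy_apt",
    ligand: str = "toy-ligand",
    role: str = "sensor",
    binding_bonus: float = 5.0,
) -> Aptamer:
    """Perfect hairpin aptamer: a complementary stem around an all-A loop."""
    rng = np.random.default_rng(spec.seed + 1)
    stem5 = _random_rna(rng, spec.aptamer_stem_length, max(spec.gc_content, 0.5))
    loop = "A" * spec.aptamer_loop_length
    sequence = stem5 + loop + reverse_complement(stem5)
    structure = (
        "(" * spec.aptamer_stem_length
        + "." * spec.aptamer_loop_length
        + ")" * spec.aptamer_stem_length
    )
    return Aptamer(
        id=id,
        ligand=ligand,
        sequence=sequence,
        reference_structure=structure,
        stem=(0, spec.aptamer_stem_length),
        role=role,
        binding_bonus=binding_bonus,
    )


def sensor_for_antisense(
    antisense: str,
    *,
    id: str,
    ligand: str,
    stem_length: int = 7,
    loop: str = "AAAA",
    binding_bonus: float = 5.0,
) -> Aptamer:
    """Build a sensor aptamer whose stem sequesters the given antisense.

    The aptamer's 5ʹ stem strand is the reverse complement of the first
    ``stem_length`` nt of the antisense, so the antisense can base-pair the
    stem in the ligand-free state — the construction used by sequestration
    switches.  The aptamer is a synthetic hairpin, not a selected sequence.
    """
    if len(antisense) < stem_length:
        raise FixtureError("antisense shorter than requested stem")
    stem5 = reverse_complement(antisense[:stem_length])
    sequence = stem5 + loop + reverse_complement(stem5)
    structure = "(" * stem_length + "." * len(loop) + ")" * stem_length
    return Aptamer(
        id=id,
        ligand=ligand,
        sequence=sequence,
        reference_structure=structure,
        stem=(0, stem_length),
        role="sensor",
        binding_bonus=binding_bonus,
    )


def fixture_library(spec: FixtureSpec) -> AptamerLibrary:
    """Packaged aptamer library plus one seeded toy aptamer."""
    lib = packaged_aptamer_library()
    lib.add(generate_toy_aptamer(spec))
    return lib


def write_fixture_bundle(outdir, spec: FixtureSpec) -> dict[str, Path]:
    """Write FASTA + annotation TSV + aptamer-library JSON for CLI use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    capped = generate_fixture_transcript(spec, id="toy_mrna_capped", capped=True)
    uncapped = generate_fixture_transcript(spec, id="toy_mrna_uncapped", capped=False)

    fasta = outdir / "transcripts.fasta"
    fasta.write_text(
        f">{capped.id}\n{capped.sequence}\n>{uncapped.id}\n{uncapped.sequence}\n"
    )
    ann = outdir / "annotations.tsv"
    lines = ["id\tutr5_end\tcds_end\tcapped"]
    for t in (capped, uncapped):
        lines.append(f"{t.id}\t{t.utr5_end}\t{t.cds_end}\t{str(t.capped).lower()}")
    ann.write_text("\n".join(lines) + "\n")

    lib = fixture_library(spec)
    lib_path = outdir / "aptamers.json"
    entries = [
        {
            "id": a.id,
            "ligand": a.ligand,
            "sequence": a.sequence,
            "reference_structure": a.reference_structure,
            "stem": list(a.stem),
            "role": a.role,
            "binding_bonus": a.binding_bonus,
        }
        for a in lib.entries.values()
    ]
    lib_path.write_text(json.dumps({"entries": entries}, indent=1))
    return {"fasta": fasta, "annotations": ann, "library": lib_path}
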