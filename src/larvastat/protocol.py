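"""Assay protocol constants for the light-dark transition test and the
MEA multi-neurotransmitter receptor paradigm."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AssayProtocol", "DEFAULT_PROTOCOL", "RecordingParadigm", "DEFAULT_PARADIGM"]


@dataclass(frozen=True)
class AssayProtocol:
    """Timing of the larval light-dark transition assay (seconds).

    20 min dark acclimation at 0 lux, 20 min light at 13,238 lux (phases L1,
    L2), then 22 min dark at 0 lux (phases D1, D2; the final 2 min are not
    binned).  Each named phase is 600 s and is summarized as five 2-min
    sums.  The visual startle response windows are the first 3 full seconds
    after the dark-to-light (VSR1, 1200 s) and light-to-dark (VSR2, 2400 s)
    transitions.
    """

    total_seconds: int = 3720
    acclimation: tuple[int, int] = (0, 1200)
    light: tuple[int, int] = (1200, 2400)
    dark: tuple[int, int] = (2400, 3720)
    phase_windows: dict = field(
        default_factory=lambda: {
            "L1": (1200, 1800),
            "L2": (1800, 2400),
            "D1": (2400, 3000),
            "D2": (3000, 3600),
        }
    )
    bin_seconds: int = 120
    bins_per_phase: int = 5
    vsr_windows: dict = field(
        default_factory=lambda: {"VSR1": (1200, 1203), "VSR2": (2400, 2403)}
    )
    light_lux: float = 13238.0

    def __post_init__(self) -> None:
        for name, (a, b) in self.phase_windows.items():
            if b - a != self.bin_seconds * self.bins_per_phase:
                raise ValueError(f"phase {name} is not {self.bins_per_phase} bins long")
        starts = sorted(w[0] for w in self.phase_windows.values())
        ends = sorted(w[1] for w in self.phase_windows.values())
        if any(s < e for s, e in zip(starts[1:], ends[:-1])):
            raise ValueError("phase windows overlap")

    @property
    def phases(self) -> list[str]:
        return list(self.phase_windows)


DEFAULT_PROTOCOL = AssayProtocol()

#: PFOS exposure series mapped to MEA recording segments 5-11 (micromolar)
PFOS_CONCENTRATIONS_UM: tuple[float, ...] = (7.78, 14.05, 25.09, 44.80, 80.0, 100.0, 120.0)


@dataclass(frozen=True)
class RecordingParadigm:
    """The 11-segment MEA recording sequence (15 min per segment).

    Segment 1: baseline; 2: GABA 10 uM; 3: antagonist (bicuculline 10 uM or
    saclofen 5 uM per well); 4: post-washout baseline, the 0 uM reference;
    5-11: sequentially increasing PFOS.
    """

    n_segments: int = 11
    baseline1: int = 1
    gaba: int = 2
    antagonist: int = 3
    baseline2: int = 4
    pfos_segments: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11)
    pfos_concentrations_um: tuple[float, ...] = PFOS_CONCENTRATIONS_UM
    segment_minutes: float = 15.0
    antagonists: tuple[str, str] = ("bicuculline", "saclofen")

    def __post_init__(self) -> None:
        if len(self.pfos_segments) != len(self.pfos_concentrations_um):
            raise ValueError("one concentration per PFOS segment required")
        if max(self.pfos_segments) != self.n_segments:
            raise ValueError("PFOS segments must end at the final segment")

    @property
    def analyzed_segments(self) -> tuple[int, ...]:
        """Segments entering the concentration-response comparison (0 uM + PFOS)."""
        return (self.baseline2, *self.pfos_segments)


DEFAULT_PARADIGM = RecordingParadigm()
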