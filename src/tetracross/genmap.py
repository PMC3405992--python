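"""Genetic maps, pathway parameters, and genotype presets.

All positions are on the genetic (cM) scale.  Physical (bp) coordinates of
the fluorescent inserts are carried as optional metadata only; nothing in
the simulation or estimation stages uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a map, parameter set, or preset is internally inconsistent."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker and centromere positions on one chromosome, in cM.

    Parameters
    ----------
    chromosome_id:
        Text label, e.g. ``"Chr5"``.
    length:
        Genetic length of the chromosome in cM.
    centromere_pos:
        Centromere position in cM; used only for rod/ring chiasma scoring.
    markers:
        Ordered ``(name, position)`` tuples, strictly increasing in
        position.  Two consecutive markers define one scoring interval.
    """

    chromosome_id: str
    length: float
    centromere_pos: float
    markers: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ConfigurationError(f"chromosome length must be > 0, got {self.length}")
        if not (0 <= self.centromere_pos <= self.length):
            raise ConfigurationError(
                f"centromere position {self.centromere_pos} outside [0, {self.length}]"
            )
        positions = [p for _, p in self.markers]
        for _, p in self.markers:
            if not (0 <= p <= self.length):
                raise ConfigurationError(f"marker position {p} outside [0, {self.length}]")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ConfigurationError("marker positions must be strictly increasing")
        object.__setattr__(self, "markers", tuple((str(n), float(p)) for n, p in self.markers))

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.markers)

    @property
    def marker_positions(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.markers)

    def marker_position(self, name: str) -> float:
        for n, p in self.markers:
            if n == name:
                return p
        raise KeyError(f"unknown marker {name!r} on {self.chromosome_id}")

    def interval_length(self, marker_a: str, marker_b: str) -> float:
        """Genetic length (cM) of the interval between two named markers."""
        return abs(self.marker_position(marker_b) - self.marker_position(marker_a))


@dataclass(frozen=True)
class PathwayParams:
    """Intensities of the two crossover pathways, per bivalent per cM.

    ``class1_intensity`` is the expected number of interfering (class I)
    crossover events per bivalent per cM; inter-event spacings follow a
    gamma distribution with shape ``interference_shape`` (1 = no
    interference, i.e. a homogeneous Poisson process).  ``class2_intensity``
    is the Poisson intensity of the non-interfering (class II) pathway.

    Calibration convention: a bivalent-level intensity of ``x`` events/cM
    over an interval of length ``L`` cM gives an expected gamete-level map
    length of ``100 * x * L / 2`` cM, because each crossover involves 2 of
    the 4 chromatids.  Hence total intensity 0.02 events/cM reproduces the
    map scale (2 crossovers per bivalent per Morgan).
    """

    class1_intensity: float = 0.017
    interference_shape: float = 5.0
    class2_intensity: float = 0.003
    obligate_co: bool = True

    def __post_init__(self) -> None:
        for name in ("class1_intensity", "class2_intensity"):
            v = getattr(self, name)
            if not (v >= 0) or v != v or v == float("inf"):
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if not (self.interference_shape > 0):
            raise ConfigurationError(
                f"interference_shape must be > 0, got {self.interference_shape}"
            )

    def scaled(self, preset: "GenotypePreset") -> "PathwayParams":
        """Apply a genotype preset's pathway multipliers."""
        return PathwayParams(
            class1_intensity=self.class1_intensity * preset.class1_multiplier,
            interference_shape=self.interference_shape,
            class2_intensity=self.class2_intensity * preset.class2_multiplier,
            obligate_co=self.obligate_co,
        )

    @property
    def total_intensity(self) -> float:
        return self.class1_intensity + self.class2_intensity


@dataclass(frozen=True)
class GenotypePreset:
    """Fractional activity of each crossover pathway for a genotype.

    Wild type keeps both pathways at full strength.  ZMM-pathway mutants
    (*hei10*, *msh4*, *zmm* generally) abolish class I but leave class II
    intact.  *spo11* abolishes all crossovers (no initiating double-strand
    breaks).  Partial class I presets (*mer3*, *mlh1*) retain a fraction of
    class I activity; their default multipliers are placeholders to be
    fitted by the user, not measured constants.
    """

    name: str
    class1_multiplier: float
    class2_multiplier: float

    def __post_init__(self) -> None:
        for name in ("class1_multiplier", "class2_multiplier"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


#: Built-in genotype presets.  mer3/mlh1 multipliers are user-tunable
#: placeholders (class I only partially lost); see docs/methods.md.
PRESETS: dict[str, GenotypePreset] = {
    "wild_type": GenotypePreset("wild_type", 1.0, 1.0),
    "hei10": GenotypePreset("hei10", 0.0, 1.0),
    "zmm": GenotypePreset("zmm", 0.0, 1.0),
    "msh4": GenotypePreset("msh4", 0.0, 1.0),
    "spo11": GenotypePreset("spo11", 0.0, 0.0),
    "mer3": GenotypePreset("mer3", 0.3, 1.0),
    "mlh1": GenotypePreset("mlh1", 0.45, 1.0),
}


def get_preset(name: str) -> GenotypePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown genotype preset {name!r}; known: {sorted(PRESETS)}"
        ) from None


# Default marker set: three linked pollen-expressed fluorophores (DsRED,
# eYFP, eCFP) on the bottom arm of chromosome 5, defining intervals I5a
# (R-Y) and I5b (Y-C).  Genetic positions are chosen so the wild-type
# interval lengths equal the measured map distances (22.84 and 12.85 cM).
DEFAULT_MARKERS = (("R", 60.0), ("Y", 82.84), ("C", 95.69))

I5A = ("R", "Y")
I5B = ("Y", "C")


def default_genome() -> list[GeneticMap]:
    """A five-chromosome genome with realistic genetic lengths.

    Lengths and centromere positions approximate the *A. thaliana* male
    genetic map (total ~500 cM, i.e. ~10 crossovers per meiosis at
    intensity 0.02/cM).  Chromosome 5 carries the R/Y/C fluorescent
    markers.
    """
    return [
        GeneticMap("Chr1", 120.0, 55.0),
        GeneticMap("Chr2", 80.0, 18.0),
        GeneticMap("Chr3", 100.0, 45.0),
        GeneticMap("Chr4", 90.0, 20.0),
        GeneticMap("Chr5", 110.0, 45.0, DEFAULT_MARKERS),
    ]


def marker_chromosome(genome: list[GeneticMap]) -> GeneticMap:
    """The chromosome carrying >= 2 markers (the tetrad-scoring target)."""
    if not genome:
        raise ConfigurationError("empty genome")
    with_markers = [g for g in genome if len(g.markers) >= 2]
    if not with_markers:
        raise ConfigurationError("no chromosome carries >= 2 markers")
    return with_markers[0]
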