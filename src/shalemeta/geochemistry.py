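"""Derived geochemical quantities for weathered organic-rich shale.

Three groups of computations:

* **Rock-Eval carbon indices.**  From the programmed-pyrolysis fractions
  S1, S2 (mg HC/g rock), S3CO2 (mg CO2/g), S3CO (mg CO/g) and TOC (wt%),
  the standard conversions give the pyrolyzable organic carbon
  ``PC = 0.083 (S1 + S2) + (12/440) S3CO2 + (12/280) S3CO``, residual
  carbon ``RC = TOC - PC``, hydrogen index ``HI = 100 S2 / TOC`` (mg HC/g
  TOC), oxygen index ``OI = 100 S3CO2 / TOC`` (mg CO2/g TOC) and the
  hydrocarbon potential ``S1 + S2``.  Kerogen is typed from HI bands
  (type I > 600, II 300-600, III 50-300, IV <= 50 mg HC/g TOC by default);
  the bands are a declared convention and configurable.

* **Sulfur speciation.**  Organic sulfur is obtained by difference from
  total, sulfate, pyritic and sulfidic (acid-volatile) sulfur; a negative
  remainder is flagged, never clamped.  Pyritic sulfur follows FeS2
  stoichiometry from measured pyrite-bound iron: S = Fe x 2 M_S / M_Fe.

* **GC-MS compound classing.**  Electron-impact spectra whose library
  match is at least 80% keep their library identity; matches of 50-79% are
  assigned to a major compound class by counting characteristic fragment
  ions among the dominant retained ions (relative intensity >= 3% of the
  base peak), requiring at least two matches, with intensity and then
  alphabetical tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_formats import FormatError, GeochemRecord

# Atomic masses (u) and the FeS2 sulfur-per-iron mass ratio.
M_S = 32.065
M_FE = 55.845
PYRITE_S_PER_FE = 2.0 * M_S / M_FE

# Carbon mass fractions of the pyrolysis signals: HC, CO2, CO.
PC_HC_FACTOR = 0.083
PC_CO2_FACTOR = 12.0 / 440.0
PC_CO_FACTOR = 12.0 / 280.0

#: HI band edges (mg HC/g TOC): type I above the first, IV at or below the last.
DEFAULT_KEROGEN_BANDS = (600.0, 300.0, 50.0)

#: Characteristic electron-impact fragment ions per compound class (m/z).
DEFAULT_CLASS_IONS: dict[str, frozenset[int]] = {
    "aromatic": frozenset({65, 77, 78, 79}),
    "aliphatic": frozenset({43, 57, 71, 85, 99}),
    "alcohol": frozenset({45, 59, 73, 87}),
    "aldehyde": frozenset({44, 58, 72}),
    "carboxylic_acid": frozenset({43, 45, 57, 59, 60, 71, 73, 85, 87}),
}

IDENTIFY_SCORE = 80.0
CLASSIFY_SCORE = 50.0
INTENSITY_CUTOFF = 0.03
TOP_N_IONS = 8
MIN_ION_MATCHES = 2


@dataclass
class KerogenIndices:
    """Rock-Eval derived indices for one sample."""

    HI: float
    OI: float
    PC: float
    RC: float
    hydrocarbon_potential: float
    kerogen_type: str


@dataclass
class SulfurSpeciation:
    """Sulfur mass balance; ``flags`` lists consistency warnings."""

    S_total: float
    S_sulfate: float
    S_pyritic: float
    S_sulfidic: float
    S_organic: float
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CompoundClassRule:
    class_name: str
    characteristic_ions: frozenset[int]

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz in self.characteristic_ions):
            raise ValueError(f"class {self.class_name!r}: ions must be positive integers")


@dataclass
class Spectrum:
    """A GC-MS peak table: ions as (m/z, intensity) pairs plus the library
    search outcome (best match name and its score, 0-100)."""

    compound_id: str
    match_score: float
    library_name: str
    peaks: list[tuple[int, float]]


@dataclass(frozen=True)
class SpectrumClassification:
    """Outcome kinds: ``identified`` (library name), ``class`` (major
    compound class), or ``unclassified``."""

    compound_id: str
    kind: str
    label: str


def rock_eval_indices(record: GeochemRecord) -> KerogenIndices:
    """Derive HI, OI, PC, RC, hydrocarbon potential and kerogen type.

    Requires TOC > 0; raises on a carbon balance where PC exceeds TOC.
    Missing S3 fractions are treated as zero for PC (and OI uses S3CO2
    only, per the standard convention).
    """
    if record.TOC is None or record.TOC <= 0:
        raise ValueError(f"{record.sample_id or 'record'}: TOC must be positive")
    s1 = record.S1 or 0.0
    s2 = record.S2 or 0.0
    s3co2 = record.S3CO2 or 0.0
    s3co = record.S3CO or 0.0
    hi = 100.0 * s2 / record.TOC
    oi = 100.0 * s3co2 / record.TOC
    pc = PC_HC_FACTOR * (s1 + s2) + PC_CO2_FACTOR * s3co2 + PC_CO_FACTOR * s3co
    if pc > record.TOC + 1e-9:
        raise ValueError(
            f"{record.sample_id or 'record'}: pyrolyzable carbon {pc:.3f} exceeds TOC {record.TOC:.3f}"
        )
    return KerogenIndices(
        HI=hi,
        OI=oi,
        PC=pc,
        RC=record.TOC - pc,
        hydrocarbon_potential=s1 + s2,
        kerogen_type=classify_kerogen(hi, oi),
    )


def classify_kerogen(
    HI: float,
    OI: float = 0.0,
    bands: Sequence[float] = DEFAULT_KEROGEN_BANDS,
) -> str:
    """Kerogen type from HI bands (boundaries assigned downward).

    Type I: HI above ``bands[0]``; II: above ``bands[1]``; III: above
    ``bands[2]``; IV otherwise.  OI is accepted for interface symmetry but
    the default typing is an HI banding.
    """
    if HI < 0 or OI < 0:
        raise ValueError("HI and OI must be non-negative")
    b1, b2, b3 = bands
    if not (b1 > b2 > b3):
        raise ValueError("bands must be strictly decreasing")
    if HI > b1:
        return "I"
    if HI > b2:
        return "II"
    if HI > b3:
        return "III"
    return "IV"


def pyritic_sulfur_from_iron(fe_wt_pct: float) -> float:
    """Pyritic sulfur (wt%) from pyrite-bound iron via FeS2 stoichiometry."""
    if fe_wt_pct < 0:
        raise ValueError("iron content must be non-negative")
    return fe_wt_pct * PYRITE_S_PER_FE


def sulfur_speciation(
    S_total: float,
    S_sulfate: float,
    S_pyritic: float,
    S_sulfidic: float,
) -> SulfurSpeciation:
    """Organic sulfur by difference, with consistency flags.

    ``S_organic = S_total - S_sulfate - S_pyritic - S_sulfidic`` as exact
    arithmetic; a negative remainder raises a flag rather than being
    clamped, so inconsistent measurements stay visible.
    """
    for name, v in (
        ("S_total", S_total), ("S_sulfate", S_sulfate),
        ("S_pyritic", S_pyritic), ("S_sulfidic", S_sulfidic),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    organic = S_total - S_sulfate - S_pyritic - S_sulfidic
    flags = []
    if organic < -1e-9:
        flags.append("components_exceed_total")
    return SulfurSpeciation(
        S_total=S_total,
        S_sulfate=S_sulfate,
        S_pyritic=S_pyritic,
        S_sulfidic=S_sulfidic,
        S_organic=organic,
        flags=flags,
    )


def default_class_rules() -> list[CompoundClassRule]:
    return [
        CompoundClassRule(name, ions) for name, ions in sorted(DEFAULT_CLASS_IONS.items())
    ]


def read_class_rules(path: str | Path) -> list[CompoundClassRule]:
    """Read class/ion rules from TSV: class_name, ``;``-joined integer m/z."""
    path = Path(path)
    rules = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, found {len(cols)}")
            try:
                ions = frozenset(int(x) for x in cols[1].split(";") if x)
                rules.append(CompoundClassRule(cols[0], ions))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rules


def shipped_class_rules() -> list[CompoundClassRule]:
    ref = resources.files("shalemeta.data").joinpath("characteristic_ions.tsv")
    with resources.as_file(ref) as path:
        return read_class_rules(path)


def classify_spectrum(
    peak_table: Sequence[tuple[int, float]],
    match_score: float,
    library_name: str,
    rules: Optional[Sequence[CompoundClassRule]] = None,
    compound_id: str = "",
    top_n: int = TOP_N_IONS,
    min_matches: int = MIN_ION_MATCHES,
    intensity_cutoff: float = INTENSITY_CUTOFF,
) -> SpectrumClassification:
    """Classify one spectrum by library score, then characteristic ions.

    Ions below ``intensity_cutoff`` of the base peak are discarded.  A
    match score of at least 80 returns the library identity regardless of
    ions; 50-79 scores to the class with the most characteristic ions among
    the *top_n* dominant retained ions (at least *min_matches* required),
    ties broken by the larger summed intensity of matching ions, then
    alphabetically; anything else is unclassified.
    """
    if not peak_table:
        raise ValueError("empty peak table")
    if not 0 <= match_score <= 100:
        raise ValueError("match_score must be in [0, 100]")
    if rules is None:
        rules = default_class_rules()

    if match_score >= IDENTIFY_SCORE:
        return SpectrumClassification(compound_id, "identified", library_name)
    if match_score < CLASSIFY_SCORE:
        return SpectrumClassification(compound_id, "unclassified", "")

    base = max(i for _, i in peak_table)
    retained = [(mz, i) for mz, i in peak_table if i >= intensity_cutoff * base]
    # dominant ions: top-N by intensity, ties broken by smaller m/z
    dominant = sorted(retained, key=lambda p: (-p[1], p[0]))[:top_n]
    dom_intensity = {mz: i for mz, i in dominant}

    best: Optional[tuple[int, float, str]] = None  # (-matches, -intensity) minimized via tuple
    for rule in sorted(rules, key=lambda r: r.class_name):
        matched = [mz for mz in dom_intensity if mz in rule.characteristic_ions]
        n = len(matched)
        if n < min_matches:
            continue
        strength = sum(dom_intensity[mz] for mz in matched)
        if best is None or (n, strength) > (best[0], best[1]):
            best = (n, strength, rule.class_name)
    if best is None:
        return SpectrumClassification(compound_id, "unclassified", "")
    return SpectrumClassification(compound_id, "class", best[2])


def classify_spectra(
    spectra: Iterable[Spectrum],
    rules: Optional[Sequence[CompoundClassRule]] = None,
    **kwargs,
) -> list[SpectrumClassification]:
    return [
        classify_spectrum(
            s.peaks, s.match_score, s.library_name, rules=rules, compound_id=s.compound_id, **kwargs
        )
        for s in spectra
    ]


# ---------------------------------------------------------------------------
# Peak table I/O (compound_id, match_score, library_name, mz:intensity ...)
# ---------------------------------------------------------------------------


def read_peak_tables(path: str | Path) -> list[Spectrum]:
    path = Path(path)
    spectra = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns, found {len(cols)}")
            try:
                peaks = []
                for pair in cols[3:]:
                    mz, intensity = pair.split(":")
                    peaks.append((int(mz), float(intensity)))
                spectra.append(
                    Spectrum(
                        compound_id=cols[0],
                        match_score=float(cols[1]),
                        library_name=cols[2],
                        peaks=peaks,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return spectra


def write_peak_tables(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#compound_id\tmatch_score\tlibrary_name\tmz:intensity...\n")
        for s in spectra:
            pairs = "\t".join(f"{mz}:{i:.4f}" for mz, i in s.peaks)
            fh.write(f"{s.compound_id}\t{s.match_score:.1f}\t{s.library_name}\t{pairs}\n")


def write_classifications(
    classifications: Iterable[SpectrumClassification], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("#compound_id\tkind\tlabel\n")
        for c in sorted(classifications, key=lambda c: c.compound_id):
            fh.write(f"{c.compound_id}\t{c.kind}\t{c.label}\n")
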