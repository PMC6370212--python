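"""Identification of decorated anthocyanins from MS/MS spectra.

The identification logic mirrors how anthocyanin glycosides are assigned in
practice from high-resolution positive-mode data:

1. the precursor m/z is decomposed over the building-block lattice
   (aglycone + bounded numbers of glycosyl and acyl residues) at ppm
   tolerance;
2. fragment ions are explained as neutral losses of residue sub-multisets
   (linkage topology is unknown, so any combination of residues may depart)
   or as free glycosyl residue ions;
3. an aglycone diagnostic fires when any fragment sits on an aglycone cation
   mass — this supports a "class-only" identification even when the
   precursor mass is internally inconsistent;
4. an optional UV/DAD record classifies the glycosylation pattern: the
   absorbance ratio E440/Emax of 3-O-glycosides is about twice that of
   3,5-di-O-glycosides.

Candidates are ranked by fraction of fragments explained, then precursor ppm
error, then simplicity, with a lexicographic tie-break for determinism.
"""

from __future__ import annotations

import bisect
import itertools
from collections import Counter
from dataclasses import dataclass, field, replace

from .masscalc import (
    ELECTRON_MASS,
    BuildingBlockLibrary,
    Composition,
    compose,
    loss_mass,
)

__all__ = [
    "Spectrum",
    "UVRecord",
    "AnnotationParams",
    "CandidateMatch",
    "FragmentExplanation",
    "Annotation",
    "DatasetSummary",
    "decompose_precursor",
    "explain_fragments",
    "detect_aglycone",
    "classify_uv",
    "annotate_spectrum",
    "annotate_dataset",
    "display_name",
]

# UV classification thresholds on E440/Emax (percent).  Operationalizes the
# "about two times greater" rule from the 52% (3-glycoside) vs 25%
# (3,5-diglycoside) exemplars, with an ambiguous band in between.
UV_3_GLYCOSIDE_MIN = 40.0
UV_35_GLYCOSIDE_MAX = 30.0


@dataclass(frozen=True)
class UVRecord:
    """UV/DAD evidence for one chromatographic peak.

    ``e440_over_emax`` is the absorbance at 440 nm divided by the absorbance
    at the visible-range maximum, expressed in percent.
    """

    lambda_max: tuple[float, ...]
    e440_over_emax: float | None = None

    def __post_init__(self) -> None:
        for lam in self.lambda_max:
            if not 200.0 <= lam <= 600.0:
                raise ValueError(f"lambda_max {lam} nm outside [200, 600]")
        if self.e440_over_emax is not None and not 0.0 <= self.e440_over_emax <= 100.0:
            raise ValueError(
                f"E440/Emax must be in [0, 100] percent, got {self.e440_over_emax}"
            )


@dataclass(frozen=True)
class Spectrum:
    """A peak-list MS/MS spectrum of a singly charged positive ion."""

    spectrum_id: str
    precursor_mz: float
    fragments: tuple[tuple[float, float], ...] = ()
    retention_time: float | None = None
    uv: UVRecord | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        for mz, intensity in self.fragments:
            if mz >= self.precursor_mz + 0.5:
                raise ValueError(
                    f"fragment m/z {mz} exceeds precursor {self.precursor_mz} + 0.5"
                )
            if intensity < 0:
                raise ValueError(f"negative fragment intensity {intensity}")

    @property
    def fragment_mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.fragments)


@dataclass(frozen=True)
class AnnotationParams:
    """Tolerances and search bounds for annotation.

    Defaults suit a high-resolution Orbitrap-class instrument: 5 ppm on the
    precursor, 10 ppm on fragments, a 10 mDa window for the aglycone
    diagnostic, and decoration bounds wide enough for polyacylated
    polyglycosides.
    """

    precursor_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 10.0
    max_glycosyl: int = 4
    max_acyl: int = 3
    aglycone_window_da: float = 0.01

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.aglycone_window_da <= 0:
            raise ValueError("aglycone window must be positive")
        if self.max_glycosyl < 0 or self.max_acyl < 0:
            raise ValueError("decoration bounds must be non-negative")


@dataclass(frozen=True)
class CandidateMatch:
    """One ranked precursor decomposition candidate.

    ``fragments_explained_fraction`` measures how much of the *observed*
    spectrum the candidate explains; ``predicted_fragment_recall`` measures
    how much of the candidate's own expected primary fragmentation series
    (single-residue losses plus the aglycone ion) is actually observed.
    The two are complementary: isobaric residue swaps (coumaroyl+hexose vs
    caffeoyl+deoxyhexose) can tie on the first but not on the second.
    """

    composition: Composition
    ppm_error: float
    fragments_explained_fraction: float = 0.0
    predicted_fragment_recall: float = 1.0


@dataclass(frozen=True)
class FragmentExplanation:
    """Explanation of a single fragment ion.

    ``kind`` is ``"loss"`` (precursor minus a residue sub-multiset; an empty
    loss multiset denotes the intact cation), ``"residue_ion"`` (a free
    glycosyl residue such as rhamnose at 146.058) or ``"unexplained"``.
    """

    mz: float
    kind: str
    loss: tuple[str, ...] = ()
    residue_id: str | None = None
    ppm_error: float | None = None

    @property
    def explained(self) -> bool:
        return self.kind != "unexplained"


@dataclass(frozen=True)
class Annotation:
    """Identification result for one spectrum (a Table-style record)."""

    spectrum_id: str
    precursor_mz: float
    candidates: tuple[CandidateMatch, ...]
    fragment_explanations: tuple[FragmentExplanation, ...]
    aglycone_detected: str | None
    uv_class: str
    display_name: str
    retention_time: float | None = None

    @property
    def top_candidate(self) -> CandidateMatch | None:
        return self.candidates[0] if self.candidates else None

    @property
    def is_class_only(self) -> bool:
        return not self.candidates and self.aglycone_detected is not None


@dataclass(frozen=True)
class DatasetSummary:
    n_spectra: int
    per_aglycone: dict[str, int]
    n_full_composition: int
    n_class_only: int
    n_unidentified: int


# --------------------------------------------------------------------------
# candidate lattice


_LATTICE_CACHE: dict[tuple, tuple[list[float], list[Composition]]] = {}


def _candidate_lattice(
    library: BuildingBlockLibrary, max_glycosyl: int, max_acyl: int
) -> tuple[list[float], list[Composition]]:
    """All compositions within the decoration bounds, sorted by cation m/z."""
    key = (library.fingerprint(), max_glycosyl, max_acyl)
    cached = _LATTICE_CACHE.get(key)
    if cached is not None:
        return cached

    glycosyl_ids = sorted(b.id for b in library.glycosyls())
    acyl_ids = sorted(b.id for b in library.acyls())

    def multisets(ids: list[str], max_total: int):
        for total in range(max_total + 1):
            yield from itertools.combinations_with_replacement(ids, total)

    compositions: list[Composition] = []
    glyco_sets = list(multisets(glycosyl_ids, max_glycosyl))
    acyl_sets = list(multisets(acyl_ids, max_acyl))
    for aglycone in library.aglycones():
        for gly in glyco_sets:
            for acyl in acyl_sets:
                compositions.append(compose(aglycone.id, gly + acyl, library))
    compositions.sort(key=lambda c: (c.cation_mz, c.sort_key()))
    masses = [c.cation_mz for c in compositions]
    _LATTICE_CACHE[key] = (masses, compositions)
    return masses, compositions


def decompose_precursor(
    mz: float,
    library: BuildingBlockLibrary,
    params: AnnotationParams = AnnotationParams(),
) -> list[Composition]:
    """All compositions whose theoretical [M]+ m/z matches ``mz`` at tolerance.

    Exhaustive within the decoration bounds.  Result is ordered by absolute
    ppm error, then fewer blocks, then lexicographic block ids.
    """
    masses, compositions = _candidate_lattice(
        library, params.max_glycosyl, params.max_acyl
    )
    tol = mz * params.precursor_tol_ppm * 1e-6
    lo = bisect.bisect_left(masses, mz - tol)
    hi = bisect.bisect_right(masses, mz + tol)
    hits = compositions[lo:hi]
    hits.sort(
        key=lambda c: (abs(c.cation_mz - mz), c.n_blocks, c.sort_key())
    )
    return hits


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


# --------------------------------------------------------------------------
# fragment explanation


def _sub_multisets(counts: Counter) -> list[tuple[str, ...]]:
    """Every sub-multiset of a decoration multiset (including the empty one)."""
    ids = sorted(counts)
    ranges = [range(counts[i] + 1) for i in ids]
    out = []
    for combo in itertools.product(*ranges):
        subset: list[str] = []
        for block_id, k in zip(ids, combo):
            subset.extend([block_id] * k)
        out.append(tuple(subset))
    return out


def explain_fragments(
    composition: Composition,
    fragments: tuple[tuple[float, float], ...] | tuple[float, ...],
    library: BuildingBlockLibrary,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[FragmentExplanation, ...]:
    """Match fragments to residue losses or free glycosyl residue ions.

    Since linkage topology is unknown, every sub-multiset of the decoration
    multiset is allowed to depart as a neutral loss.  The smallest-|ppm|
    match within the fragment tolerance wins; unmatched fragments are
    labelled unexplained.
    """
    # Accept either (mz, intensity) pairs or bare m/z values.
    mzs = [f[0] if isinstance(f, tuple) else float(f) for f in fragments]

    loss_targets: list[tuple[float, tuple[str, ...]]] = []
    for subset in _sub_multisets(composition.decoration_counts()):
        loss_targets.append(
            (composition.cation_mz - loss_mass(subset, library), subset)
        )
    residue_targets: list[tuple[float, str]] = []
    for block_id in sorted(set(composition.decorations)):
        block = library[block_id]
        if block.block_class == "glycosyl":
            residue_targets.append((block.residue_mass, block_id))

    explanations = []
    for mz in mzs:
        tol = mz * params.fragment_tol_ppm * 1e-6
        best: FragmentExplanation | None = None
        best_err = tol
        for target, subset in loss_targets:
            err = abs(mz - target)
            if err <= best_err:
                best_err = err
                best = FragmentExplanation(
                    mz=mz, kind="loss", loss=subset, ppm_error=ppm_error(mz, target)
                )
        for target, block_id in residue_targets:
            err = abs(mz - target)
            if err < best_err:
                best_err = err
                best = FragmentExplanation(
                    mz=mz,
                    kind="residue_ion",
                    residue_id=block_id,
                    ppm_error=ppm_error(mz, target),
                )
        explanations.append(best or FragmentExplanation(mz=mz, kind="unexplained"))
    return tuple(explanations)


def detect_aglycone(
    fragments: tuple[tuple[float, float], ...] | tuple[float, ...],
    library: BuildingBlockLibrary,
    params: AnnotationParams = AnnotationParams(),
) -> str | None:
    """Aglycone whose cation mass lies within the Da window of any fragment.

    The diagnostic ion (e.g. pelargonidin at m/z 271.060) terminates every
    anthocyanin fragmentation series, so its presence identifies the pigment
    class even when the precursor cannot be decomposed.
    """
    mzs = [f[0] if isinstance(f, tuple) else float(f) for f in fragments]
    best_id: str | None = None
    best_err = params.aglycone_window_da
    for aglycone in sorted(library.aglycones(), key=lambda b: b.id):
        target = aglycone.residue_mass - ELECTRON_MASS
        for mz in mzs:
            err = abs(mz - target)
            if err <= best_err:
                best_err = err
                best_id = aglycone.id
    return best_id


def classify_uv(uv: UVRecord | None) -> str:
    """Glycosylation pattern from the E440/Emax ratio.

    3-O-glycosides show a ratio roughly twice that of 3,5-di-O-glycosides;
    the decision thresholds (>= 40% vs <= 30%, percent scale) bracket the
    published 52% / 25% exemplars with an ambiguous band between.
    """
    if uv is None or uv.e440_over_emax is None:
        return "absent"
    ratio = uv.e440_over_emax
    if not 0.0 <= ratio <= 100.0:
        raise ValueError(f"E440/Emax ratio {ratio} outside [0, 100]")
    if ratio >= UV_3_GLYCOSIDE_MIN:
        return "3-glycoside"
    if ratio <= UV_35_GLYCOSIDE_MAX:
        return "3,5-glycoside"
    return "ambiguous"


# --------------------------------------------------------------------------
# naming

_SUGAR_NAMES = {"hexose": "hexoside", "deoxyhexose": "deoxyhexoside"}
_GREEK = {2: "di", 3: "tri", 4: "tetra"}


def display_name(composition: Composition) -> str:
    """Human-readable label for a composition.

    Labels are cosmetic: mass decomposition cannot resolve attachment
    positions or sugar stereochemistry, so names describe the residue
    multiset (with the hexose+deoxyhexose pair labelled rutinoside-style).
    """
    counts = composition.decoration_counts()
    if not counts:
        return composition.aglycone_id
    parts: list[str] = []
    if counts.get("hexose") == 1 and counts.get("deoxyhexose") == 1:
        parts.append("O-rutinoside-type (hexose+deoxyhexose)")
        del counts["hexose"], counts["deoxyhexose"]
    for block_id in sorted(counts):
        n = counts[block_id]
        suffix = _SUGAR_NAMES.get(block_id, block_id)
        parts.append(f"O-{_GREEK.get(n, '')}{suffix}" if n > 1 or block_id in _SUGAR_NAMES
                     else f"{block_id}")
    return f"{composition.aglycone_id} " + " ".join(parts)


# --------------------------------------------------------------------------
# spectrum- and dataset-level drivers


def _predicted_recall(
    composition: Composition,
    fragment_mzs: list[float],
    library: BuildingBlockLibrary,
    params: AnnotationParams,
) -> float:
    """Fraction of the candidate's primary-loss series seen in the spectrum.

    The expected primary series is one ion per distinct single-residue loss
    plus the aglycone ion; an undecorated candidate has an empty series and
    recall 1 by convention.
    """
    predicted: list[float] = []
    for block_id in sorted(set(composition.decorations)):
        predicted.append(composition.cation_mz - library[block_id].residue_mass)
    if composition.decorations:
        predicted.append(
            library[composition.aglycone_id].residue_mass - ELECTRON_MASS
        )
    predicted = sorted(set(round(mz, 6) for mz in predicted))
    if not predicted:
        return 1.0
    seen = 0
    for target in predicted:
        tol = target * params.fragment_tol_ppm * 1e-6
        if any(abs(mz - target) <= tol for mz in fragment_mzs):
            seen += 1
    return seen / len(predicted)


def annotate_spectrum(
    spectrum: Spectrum,
    library: BuildingBlockLibrary,
    params: AnnotationParams = AnnotationParams(),
) -> Annotation:
    """Full annotation of one spectrum.

    Candidates are ranked by (descending fraction of fragments explained,
    descending predicted-fragment recall, ascending |precursor ppm error|,
    ascending block count, lexicographic block ids).  When no composition
    passes the precursor tolerance but the aglycone diagnostic fires, a
    class-only annotation is emitted.
    """
    compositions = decompose_precursor(spectrum.precursor_mz, library, params)
    fragment_mzs = list(spectrum.fragment_mzs)
    candidates: list[CandidateMatch] = []
    explanations_by_comp: dict[Composition, tuple[FragmentExplanation, ...]] = {}
    for comp in compositions:
        expl = explain_fragments(comp, spectrum.fragments, library, params)
        explanations_by_comp[comp] = expl
        fraction = (
            sum(e.explained for e in expl) / len(expl) if expl else 1.0
        )
        candidates.append(
            CandidateMatch(
                composition=comp,
                ppm_error=ppm_error(spectrum.precursor_mz, comp.cation_mz),
                fragments_explained_fraction=fraction,
                predicted_fragment_recall=_predicted_recall(
                    comp, fragment_mzs, library, params
                ),
            )
        )
    candidates.sort(
        key=lambda c: (
            -c.fragments_explained_fraction,
            -c.predicted_fragment_recall,
            abs(c.ppm_error),
            c.composition.n_blocks,
            c.composition.sort_key(),
        )
    )
    aglycone = detect_aglycone(spectrum.fragments, library, params)
    if candidates:
        top = candidates[0]
        frag_expl = explanations_by_comp[top.composition]
        name = display_name(top.composition)
    else:
        frag_expl = tuple(
            FragmentExplanation(mz=mz, kind="unexplained")
            for mz in spectrum.fragment_mzs
        )
        name = f"{aglycone} derivative (class-only)" if aglycone else "unidentified"
    return Annotation(
        spectrum_id=spectrum.spectrum_id,
        precursor_mz=spectrum.precursor_mz,
        candidates=tuple(candidates),
        fragment_explanations=frag_expl,
        aglycone_detected=aglycone,
        uv_class=classify_uv(spectrum.uv),
        display_name=name,
        retention_time=spectrum.retention_time,
    )


def annotate_dataset(
    spectra: list[Spectrum],
    library: BuildingBlockLibrary,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[list[Annotation], DatasetSummary]:
    """Annotate a list of spectra and summarize detections per aglycone class."""
    ids = [s.spectrum_id for s in spectra]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate spectrum ids: {sorted(dupes)}")
    annotations = [annotate_spectrum(s, library, params) for s in spectra]
    per_aglycone: Counter[str] = Counter()
    n_full = n_class_only = n_unidentified = 0
    for ann in annotations:
        if ann.top_candidate is not None:
            n_full += 1
            per_aglycone[ann.top_candidate.composition.aglycone_id] += 1
        elif ann.aglycone_detected is not None:
            n_class_only += 1
            per_aglycone[ann.aglycone_detected] += 1
        else:
            n_unidentified += 1
    summary = DatasetSummary(
        n_spectra=len(spectra),
        per_aglycone=dict(per_aglycone),
        n_full_composition=n_full,
        n_class_only=n_class_only,
        n_unidentified=n_unidentified,
    )
    return annotations, summary
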