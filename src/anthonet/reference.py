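"""Published reference spectra of orange-gentian petal anthocyanins.

Eleven pelargonidin derivatives reported from petals of *Gentiana lutea* var.
*aurantiaca* by HPLC-ESI-MS/MS (positive mode, [M]+ ions), transcribed from
the published identification table: precursor m/z, fragment m/z series,
retention time, the reported molecular formula and assignment, and the
developmental stages (S1 budlet, S3 mature bud, S5 open flower) in which each
compound was detected.  Fragment intensities were not published; descending
placeholder intensities are used (annotation never uses intensity).

Two peaks additionally carry published E440/Emax ratios (25% for the
3,5-diglucoside, 52% for the 3-glucoside), the worked exemplars of the UV
glycosylation rule.

These records serve as a desk-scale regression dataset: several entries are
internally inconsistent in the original report (see the ``consistent`` flag)
and the annotation engine is expected to flag them, not repair them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import Spectrum, UVRecord

__all__ = [
    "ReferencePeak",
    "REFERENCE_PEAKS",
    "reference_spectra",
    "REPORTED_AGLYCONE_MZ",
    "REPORTED_RHAMNOSE_FRAGMENT_MZ",
    "REPORTED_MALONYLHEXOSE_LOSS",
    "REPORTED_CAFFEOYLHEXOSE_LOSS",
]

#: Reported m/z of the pelargonidin aglycone ion.
REPORTED_AGLYCONE_MZ = 271.06008
#: Reported free-rhamnose residue ion (peak 3 fragment).
REPORTED_RHAMNOSE_FRAGMENT_MZ = 146.05790
#: Reported neutral-loss masses from the peak-7 walk-through.
REPORTED_MALONYLHEXOSE_LOSS = 248.05321
REPORTED_CAFFEOYLHEXOSE_LOSS = 324.08451


@dataclass(frozen=True)
class ReferencePeak:
    """One row of the published identification table."""

    peak: int
    rt_min: float
    precursor_mz: float
    fragment_mzs: tuple[float, ...]
    formula: str  # reported molecular formula (Hill notation)
    assignment: str  # reported compound name
    stages: tuple[str, ...]
    e440_over_emax: float | None = None
    lambda_max: tuple[float, ...] = ()
    #: True when the reported precursor m/z agrees with the reported formula
    #: within 5 ppm.
    consistent: bool = True
    #: True when the reported precursor m/z is reachable on the building-block
    #: lattice at 5 ppm.  Peak 10 is consistent but NOT decomposable: its
    #: reported formula is two hydrogens short of any aglycone+residue sum
    #: (and of its own assignment name), so the engine reports it class-only
    #: rather than repairing the record.
    decomposable: bool = True


REFERENCE_PEAKS: tuple[ReferencePeak, ...] = (
    ReferencePeak(
        1, 6.88, 741.22180, (579.16992, 433.11237, 271.05966),
        "C33H41O19", "pelargonidin 3-O-rutinoside-5-O-glucoside",
        ("S3", "S5"), lambda_max=(274, 426, 498),
    ),
    ReferencePeak(
        2, 8.61, 595.16516, (433.11273, 271.05972),
        "C27H31O15", "pelargonidin 3,5-O-diglucoside",
        ("S1", "S3", "S5"), e440_over_emax=25.0, lambda_max=(282, 497),
    ),
    ReferencePeak(
        3, 11.15, 579.17078, (433.11307, 271.05981, 146.05790),
        "C27H31O14", "pelargonidin 3-O-rutinoside",
        ("S1", "S3", "S5"), lambda_max=(498,),
    ),
    ReferencePeak(
        4, 12.53, 433.11203, (271.05969,),
        "C21H21O10", "pelargonidin 3-O-glucoside",
        ("S1", "S3", "S5"), e440_over_emax=52.0, lambda_max=(498,),
    ),
    ReferencePeak(
        5, 12.73, 1094.29358, (932.23883, 771.21368, 433.11273, 271.06000),
        "C52H55O26",
        "pelargonidin 3-O-[2-O-(6-feruloyl-glucosyl)-6-caffeoyl-glucoside]-"
        "5-O-glucoside",
        ("S3", "S5"), lambda_max=(282, 496), consistent=False, decomposable=False,
    ),
    ReferencePeak(
        6, 13.07, 1079.30284, (932.23871, 771.21368, 433.11273, 271.05972),
        "C52H55O25",
        "pelargonidin 3-O-[2-O-(6-feruloyl-glucosyl)-6-coumaroyl-glucoside]-"
        "5-O-glucoside",
        ("S3", "S5"), lambda_max=(447, 496),
    ),
    ReferencePeak(
        7, 13.87, 843.22095,
        (681.16675, 595.16333, 519.11456, 433.11392, 271.06033),
        "C39H39O21",
        "pelargonidin 3-O-(6-caffeoyl-glucoside)-5-O-(6-malonyl-glucoside)",
        ("S3", "S5"), lambda_max=(275, 366, 500), consistent=False,
    ),
    ReferencePeak(
        8, 14.28, 827.21936, (579.17004, 519.11230, 271.05972),
        "C36H43O22",
        "pelargonidin 3-O-(6-coumaroyl-glucoside)-5-(4-malonyl-glucoside)",
        ("S3", "S5"), lambda_max=(492,), consistent=False, decomposable=False,
    ),
    ReferencePeak(
        9, 14.94, 681.16565, (519.11298, 433.11243, 271.05963),
        "C30H33O18",
        "pelargonidin 3-O-(6-malonyl-glucoside)-5-O-glucoside",
        ("S3", "S5"), lambda_max=(447, 496),
    ),
    ReferencePeak(
        10, 15.22, 517.09755, (433.11307, 271.06073),
        "C24H21O13", "pelargonidin 3-O-(6-malonyl-glucoside)",
        ("S1", "S3", "S5"), lambda_max=(282, 496), decomposable=False,
    ),
    ReferencePeak(
        11, 15.66, 579.15012, (433.11307, 271.05957),
        "C30H27O12", "pelargonidin 3-O-(6-coumaroyl)glucoside",
        ("S1", "S3", "S5"), lambda_max=(447, 496),
    ),
)


def reference_spectra() -> list[Spectrum]:
    """The reference peaks as :class:`~anthonet.annotate.Spectrum` objects.

    Placeholder descending intensities (100, 90, ...) stand in for the
    unpublished fragment intensities.
    """
    spectra = []
    for peak in REFERENCE_PEAKS:
        uv = None
        if peak.lambda_max or peak.e440_over_emax is not None:
            uv = UVRecord(
                lambda_max=tuple(float(x) for x in peak.lambda_max),
                e440_over_emax=peak.e440_over_emax,
            )
        spectra.append(
            Spectrum(
                spectrum_id=f"peak{peak.peak}",
                precursor_mz=peak.precursor_mz,
                fragments=tuple(
                    (mz, 100.0 - 10.0 * i) for i, mz in enumerate(peak.fragment_mzs)
                ),
                retention_time=peak.rt_min,
                uv=uv,
            )
        )
    return spectra
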