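"""Study orchestration: measure → classify → kinematics → statistics.

``run_study`` turns a cohort (landmark-level or pre-measured) into a
:class:`StudyReport` with the structure of a clinical morphometry results
section: per-group/position angle statistics with significance tests
(``table1``), condyle/disc coordinate statistics (``table2``), group-mean
movement vectors between bite positions, recapture counts for the treated
positions, mandibular posture summaries and, optionally, reliability ICCs
from replicate measurement sessions.

All numbers are pure functions of the cohort; significance is reported as
explicit pair → p-value maps, with :func:`significance_letters` available
to render the compact letter annotations used in printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

from .classify import DiscPosition, RecaptureResult, classify_disc_position, recapture_rate
from .errors import EmptyGroupError
from .kinematics import (
    Cohort,
    DisplacementVector,
    DIAGNOSES,
    POSITIONS,
    group_mean_displacement,
    mandibular_posture_summary,
    measure_cohort,
)
from .stats import (
    AnovaResult,
    DescriptiveStats,
    IccResult,
    describe,
    icc,
    one_way_anova_lsd,
    t_test,
)

__all__ = [
    "StudyReport",
    "run_study",
    "reliability_icc",
    "significance_letters",
    "render_markdown",
]

COORD_VARS = ("condyle_x", "condyle_y", "disc_x", "disc_y")
MOVEMENT_SPANS = ((1, 2), (1, 3))


def _coord(measurement, var: str) -> float:
    structure, axis = var.rsplit("_", 1)
    return getattr(getattr(measurement, structure), axis)


@dataclass
class StudyReport:
    """All derived study results; every cell is an operation output."""

    group_ns: Dict[str, int]
    #: group -> position -> angle DescriptiveStats
    table1: Dict[str, Dict[int, DescriptiveStats]]
    #: group -> ANOVA of angles across positions (LSD pairwise on position pairs)
    table1_position_tests: Dict[str, AnovaResult]
    #: position -> (group_a, group_b) -> two-sample t-test p on angles
    table1_group_tests: Dict[int, Dict[Tuple[str, str], float]]
    #: group -> position -> variable -> DescriptiveStats (mm)
    table2: Dict[str, Dict[int, Dict[str, DescriptiveStats]]]
    #: group -> variable -> ANOVA across positions
    table2_position_tests: Dict[str, Dict[str, AnovaResult]]
    #: position -> variable -> (group_a, group_b) -> t-test p
    table2_group_tests: Dict[int, Dict[str, Dict[Tuple[str, str], float]]]
    #: group -> structure -> "P{a}->P{b}" -> DisplacementVector
    movements: Dict[str, Dict[str, Dict[str, DisplacementVector]]]
    #: treated position -> RecaptureResult (DDwR joints, displaced baselines)
    recapture: Dict[int, RecaptureResult]
    #: joints excluded from recapture because the baseline was not displaced
    recapture_excluded: int
    #: posture change descriptives over patients with metadata
    posture: Dict[str, DescriptiveStats] = field(default_factory=dict)
    reliability: Dict[str, IccResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready dict; tuple keys flattened, empty sections omitted."""

        def conv(obj):
            if isinstance(obj, dict):
                return {
                    (str(k) if isinstance(k, (str, int)) else "|".join(map(str, k))): conv(v)
                    for k, v in obj.items()
                }
            if hasattr(obj, "__dataclass_fields__"):
                d = asdict(obj)
                return conv(d)
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        out = {}
        for name, value in self.__dict__.items():
            if value in ({}, None) and name in ("posture", "reliability"):
                continue
            out[name] = conv(value)
        return out


def _angles(records, pos: int) -> List[float]:
    return [r.measurements[pos].angle for r in records if pos in r.measurements]


def run_study(
    cohort: Cohort,
    alpha: float = 0.05,
    paired: bool = False,
    fh_offset_deg: float = 0.0,
) -> StudyReport:
    """Compute the full study report for a cohort.

    ``paired`` switches the across-position comparisons from the one-way
    ANOVA (the conventional between-sample analysis, default) to paired
    t-tests on joints with complete data; the default mirrors standard
    reporting even though positions are within-joint.
    """
    if len(cohort) == 0:
        raise EmptyGroupError("cannot analyze an empty cohort")
    needs_measure = any(
        rec.landmarks and not rec.measurements for rec in cohort.records
    )
    if needs_measure:
        measure_cohort(cohort, fh_offset_deg)
    if all(not rec.measurements for rec in cohort.records):
        raise EmptyGroupError("no measurable joints: neither measurements nor landmarks")

    groups = [g for g in DIAGNOSES if cohort.group(g)]
    group_ns = {g: len(cohort.group(g)) for g in groups}
    if not any(n >= 2 for n in group_ns.values()):
        raise EmptyGroupError("need at least one diagnosis group with >= 2 joints")

    table1: Dict[str, Dict[int, DescriptiveStats]] = {}
    table2: Dict[str, Dict[int, Dict[str, DescriptiveStats]]] = {}
    t1_pos_tests: Dict[str, AnovaResult] = {}
    t2_pos_tests: Dict[str, Dict[str, AnovaResult]] = {}
    for g in groups:
        recs = cohort.group(g)
        table1[g] = {}
        table2[g] = {}
        for pos in POSITIONS:
            ang = _angles(recs, pos)
            if ang:
                table1[g][pos] = describe(ang)
                table2[g][pos] = {
                    v: describe([_coord(r.measurements[pos], v) for r in recs
                                 if pos in r.measurements])
                    for v in COORD_VARS
                }
        pos_angle_groups = [
            _angles(recs, pos) for pos in POSITIONS if len(_angles(recs, pos)) >= 2
        ]
        if len(pos_angle_groups) >= 2:
            t1_pos_tests[g] = one_way_anova_lsd(pos_angle_groups)
            t2_pos_tests[g] = {}
            for v in COORD_VARS:
                cols = [
                    [_coord(r.measurements[pos], v) for r in recs if pos in r.measurements]
                    for pos in POSITIONS
                ]
                cols = [c for c in cols if len(c) >= 2]
                if len(cols) >= 2:
                    t2_pos_tests[g][v] = one_way_anova_lsd(cols)

    t1_group_tests: Dict[int, Dict[Tuple[str, str], float]] = {}
    t2_group_tests: Dict[int, Dict[str, Dict[Tuple[str, str], float]]] = {}
    for pos in POSITIONS:
        pairs: Dict[Tuple[str, str], float] = {}
        coord_pairs: Dict[str, Dict[Tuple[str, str], float]] = {v: {} for v in COORD_VARS}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = _angles(cohort.group(ga), pos)
                b = _angles(cohort.group(gb), pos)
                if len(a) >= 2 and len(b) >= 2:
                    pairs[(ga, gb)] = t_test(a, b).p
                    for v in COORD_VARS:
                        av = [_coord(r.measurements[pos], v) for r in cohort.group(ga)
                              if pos in r.measurements]
                        bv = [_coord(r.measurements[pos], v) for r in cohort.group(gb)
                              if pos in r.measurements]
                        coord_pairs[v][(ga, gb)] = t_test(av, bv).p
        if pairs:
            t1_group_tests[pos] = pairs
            t2_group_tests[pos] = {v: d for v, d in coord_pairs.items() if d}

    movements: Dict[str, Dict[str, Dict[str, DisplacementVector]]] = {}
    for g in groups:
        per_struct: Dict[str, Dict[str, DisplacementVector]] = {}
        for structure in ("condyle", "disc"):
            spans: Dict[str, DisplacementVector] = {}
            for a, b in MOVEMENT_SPANS:
                try:
                    spans[f"P{a}->P{b}"] = group_mean_displacement(
                        cohort, structure, a, b, group=g
                    )
                except EmptyGroupError:
                    continue
            if spans:
                per_struct[structure] = spans
        if per_struct:
            movements[g] = per_struct

    recapture: Dict[int, RecaptureResult] = {}
    excluded = 0
    ddwr = cohort.group("DDwR")
    displaced = [
        r for r in ddwr
        if 1 in r.measurements
        and classify_disc_position(r.measurements[1].angle).status
        is DiscPosition.ANTERIOR_DISPLACED
    ]
    excluded = len(ddwr) - len(displaced)
    for treated in (2, 3):
        usable = [r for r in displaced if treated in r.measurements]
        if usable:
            recapture[treated] = recapture_rate(
                [r.measurements[treated].angle for r in usable],
                [r.measurements[1].angle for r in usable],
            )

    posture: Dict[str, DescriptiveStats] = {}
    if cohort.meta:
        summaries = [mandibular_posture_summary(m) for m in cohort.meta.values()]
        posture = {
            key: describe([s[key] for s in summaries])
            for key in ("vertical_opening_change", "protrusion_change")
        }

    return StudyReport(
        group_ns=group_ns,
        table1=table1,
        table1_position_tests=t1_pos_tests,
        table1_group_tests=t1_group_tests,
        table2=table2,
        table2_position_tests=t2_pos_tests,
        table2_group_tests=t2_group_tests,
        movements=movements,
        recapture=recapture,
        recapture_excluded=excluded,
        posture=posture,
    )


def reliability_icc(
    replicate_cohorts: List[Cohort],
    variables: Tuple[str, ...] = ("angle",) + COORD_VARS,
    model: str = "twoway_random_absolute",
    fh_offset_deg: float = 0.0,
) -> Dict[str, IccResult]:
    """Intra-/inter-observer reliability from replicate measurement sets.

    Each cohort is one rater/session over the same joints; ICC is computed
    per derived variable on the joint-position × replicate matrix."""
    if len(replicate_cohorts) < 2:
        raise EmptyGroupError("reliability needs at least two replicate cohorts")
    for c in replicate_cohorts:
        measure_cohort(c, fh_offset_deg)
    base = replicate_cohorts[0]
    keys = [
        (rec.joint_id, pos)
        for rec in base.records
        for pos in sorted(rec.measurements)
    ]
    by_id = [{r.joint_id: r for r in c.records} for c in replicate_cohorts]
    out: Dict[str, IccResult] = {}
    for var in variables:
        matrix = []
        for joint_id, pos in keys:
            row = []
            for lookup in by_id:
                rec = lookup.get(joint_id)
                if rec is None or pos not in rec.measurements:
                    row = None
                    break
                m = rec.measurements[pos]
                row.append(m.angle if var == "angle" else _coord(m, var))
            if row is not None:
                matrix.append(row)
        out[var] = icc(matrix, model=model)
    return out


def significance_letters(
    pairwise: Dict[Tuple, float], labels: List, alpha: float = 0.05
) -> Dict[str, str]:
    """Compact letter annotations: each pair significant at ``alpha`` gets
    one shared letter on both members, in the style of printed tables where
    'the same letter marks a significant difference between the two'."""
    marks: Dict[str, List[str]] = {str(lbl): [] for lbl in labels}
    letter = ord("a")
    for (i, j), p in sorted(pairwise.items(), key=lambda kv: str(kv[0])):
        if p < alpha:
            a = labels[i] if isinstance(i, int) else i
            b = labels[j] if isinstance(j, int) else j
            marks[str(a)].append(chr(letter))
            marks[str(b)].append(chr(letter))
            letter += 1
    return {k: "".join(v) for k, v in marks.items()}


def render_markdown(report: StudyReport) -> str:
    """Render a compact human-readable summary of a study report."""
    lines = ["# Study report", ""]
    lines.append("## Group sizes")
    for g, n in report.group_ns.items():
        lines.append(f"- {g}: {n} joints")
    lines.append("")
    lines.append("## Disc-condyle angles (degrees, mean ± SD)")
    for g, per_pos in report.table1.items():
        for pos, ds in sorted(per_pos.items()):
            sd = f" ± {ds.sd:.1f}" if ds.sd is not None else ""
            lines.append(f"- {g}, position {pos}: {ds.mean:.1f}{sd} (n={ds.n})")
    lines.append("")
    if report.recapture:
        lines.append("## Disc recapture (displaced DDwR baselines)")
        for pos, rr in sorted(report.recapture.items()):
            lines.append(f"- position {pos}: {rr.count}/{rr.total} = {rr.pct:.1f}%")
        if report.recapture_excluded:
            lines.append(
                f"- excluded (baseline not anteriorly displaced): {report.recapture_excluded}"
            )
        lines.append("")
    if report.movements:
        lines.append("## Mean movements")
        for g, per_struct in report.movements.items():
            for structure, spans in per_struct.items():
                for span, vec in spans.items():
                    lines.append(f"- {g} {structure} {span}: {vec.describe()}")
        lines.append("")
    if report.posture:
        lines.append("## Mandibular posture changes (mm)")
        for key, ds in report.posture.items():
            sd = f" ± {ds.sd:.2f}" if ds.sd is not None else ""
            lines.append(f"- {key}: {ds.mean:.2f}{sd} (n={ds.n})")
        lines.append("")
    if report.reliability:
        lines.append("## Reliability (ICC)")
        for var, res in report.reliability.items():
            lines.append(
                f"- {var}: ICC={res.icc:.3f} ({res.model}, "
                f"{res.n_subjects}x{res.n_raters})"
            )
        lines.append("")
    return "\n".join(lines)
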