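"""Structure-check alerts, author responses and submission gating.

Mirrors the checkcif-style workflow: running a battery of checks over a
submitted data block produces classed alerts — **A** (extreme outlier),
**B** (significant outlier), **C** (minor note).  A and B alerts are
*serious*: a submission is admitted into review only when every serious
alert carries a machine-readable author response, which travels inside
the CIF itself as a ``_vrf_``-prefixed item named after the alert code.

Checks run in a fixed order so reports are deterministic:

1. completeness against a journal profile of required tags,
2. dictionary validation findings, re-expressed as C alerts,
3. displacement-ellipsoid elongation per anisotropic site (the
   PLAT213-style check: extreme axial ratios may indicate unresolved
   disorder),
4. bond-length plausibility against summed covalent radii,
5. occupancy sanity over disorder assemblies.

Sites listed in ``config.excluded_labels`` (e.g. solvent ions that are
deliberately not fully refined) are skipped by the ellipsoid check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cif_syntax import DataBlock
from .dictionary import Dictionary, validate_block
from .geometry import (
    AtomSite,
    UnitCell,
    cell_from_block,
    orthogonalization,
    sites_from_block,
)

__all__ = [
    "Alert",
    "AlertResponse",
    "ValidationReport",
    "CheckConfig",
    "u_cif_to_cartesian",
    "adp_elongation_check",
    "run_checks",
    "collect_responses",
    "gate_submission",
    "render_report",
]


@dataclass(frozen=True)
class Alert:
    """A single validation finding with a checkcif-style code."""

    code: str  # e.g. PLAT213_ALERT_2_B
    severity: str  # A | B | C
    message: str
    subject: str  # offending tag or atom label
    explanation: str = ""

    @property
    def serious(self) -> bool:
        return self.severity in ("A", "B")


@dataclass(frozen=True)
class AlertResponse:
    """A machine-readable author response to one alert code."""

    code: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("response text must be non-empty")


@dataclass
class ValidationReport:
    alerts: list[Alert] = field(default_factory=list)
    responses: list[AlertResponse] = field(default_factory=list)
    admitted: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def serious_alerts(self) -> list[Alert]:
        return [a for a in self.alerts if a.serious]


@dataclass
class CheckConfig:
    """Tunable journal policy for the checks.

    The ellipsoid axial-ratio thresholds (B at 4, A at 8) and the bond
    deviation bands (C beyond ±0.15 Å, B beyond ±0.30 Å from the summed
    covalent radii) are policy defaults, not physics; all are exposed.
    """

    adp_ratio_b: float = 4.0
    adp_ratio_a: float = 8.0
    bond_dev_c: float = 0.15
    bond_dev_b: float = 0.30
    bond_search_tol: float = 0.40
    occupancy_tol: float = 0.02
    required_tags: tuple[str, ...] = (
        "_cell_length_a",
        "_cell_length_b",
        "_cell_length_c",
        "_cell_angle_alpha",
        "_cell_angle_beta",
        "_cell_angle_gamma",
        "_cell_volume",
        "_chemical_formula_sum",
    )
    excluded_labels: frozenset[str] = frozenset()


_EXPLANATIONS = {
    "PLAT213": "Atom has an unusually elongated displacement ellipsoid; "
    "this may indicate unresolved disorder in the crystal.",
    "ADPPOS": "The anisotropic displacement tensor is not positive definite "
    "and cannot describe a physical probability distribution.",
    "COMP01": "A data item required by the journal profile is missing.",
    "DICT01": "The item violates its dictionary definition.",
    "BOND01": "An inferred bond length deviates from the sum of covalent radii.",
    "OCCU01": "Occupancies of the disorder groups in an assembly do not sum to 1.",
}


def u_cif_to_cartesian(cell: UnitCell, u_aniso: np.ndarray) -> np.ndarray:
    """Transform a CIF-convention displacement tensor to Cartesian Å².

    ``U_cart = A N U N Aᵀ`` where ``A`` is the orthogonalization matrix and
    ``N = diag(a*, b*, c*)`` holds the reciprocal cell lengths.  The input
    must be symmetric; the output is symmetrised against round-off.
    """
    u = np.asarray(u_aniso, dtype=float)
    if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-10):
        raise ValueError("u_aniso must be a symmetric 3x3 tensor")
    a = orthogonalization(cell)
    g_star = np.linalg.inv(a.T @ a)
    n = np.diag(np.sqrt(np.diag(g_star)))
    u_cart = a @ n @ u @ n @ a.T
    return (u_cart + u_cart.T) / 2.0


def adp_elongation_check(
    cell: UnitCell, site: AtomSite, config: Optional[CheckConfig] = None
) -> Optional[Alert]:
    """PLAT213-style check of the displacement-ellipsoid axial ratio.

    The ratio r = λ_max/λ_min of the Cartesian-U eigenvalues triggers a
    B alert above ``adp_ratio_b`` and an A alert above ``adp_ratio_a``;
    a non-positive-definite tensor is its own A alert.
    """
    config = config or CheckConfig()
    if site.u_aniso is None:
        return None
    u_cart = u_cif_to_cartesian(cell, site.u_aniso)
    eig = np.linalg.eigvalsh(u_cart)
    if eig[0] <= 0.0:
        return Alert(
            "ADPPOS_ALERT_1_A",
            "A",
            f"displacement tensor of {site.label} is not positive definite",
            site.label,
            _EXPLANATIONS["ADPPOS"],
        )
    ratio = float(eig[-1] / eig[0])
    if ratio > config.adp_ratio_a:
        sev = "A"
    elif ratio > config.adp_ratio_b:
        sev = "B"
    else:
        return None
    return Alert(
        f"PLAT213_ALERT_2_{sev}",
        sev,
        f"atom {site.label} has an unusually elongated displacement "
        f"ellipsoid (axial ratio {ratio:.2f})",
        site.label,
        _EXPLANATIONS["PLAT213"],
    )


def run_checks(
    block: DataBlock,
    dictionary: Optional[Dictionary] = None,
    config: Optional[CheckConfig] = None,
) -> ValidationReport:
    """Assemble the validation report (alerts only) for one data block."""
    from .connectivity import DEFAULT_RADII, infer_bonds  # local: avoids cycle

    config = config or CheckConfig()
    alerts: list[Alert] = []

    # 1. completeness against the journal profile
    for tag in config.required_tags:
        if block.get(tag) is None:
            alerts.append(
                Alert(
                    "COMP01_ALERT_1_A",
                    "A",
                    f"required item {tag} is missing",
                    tag,
                    _EXPLANATIONS["COMP01"],
                )
            )

    # 2. dictionary findings as C alerts
    if dictionary is not None:
        for v in validate_block(block, dictionary):
            alerts.append(
                Alert(
                    "DICT01_ALERT_1_C",
                    "C",
                    str(v),
                    v.tag,
                    _EXPLANATIONS["DICT01"],
                )
            )

    try:
        cell = cell_from_block(block)
        sites = sites_from_block(block)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"block {block.name!r} does not parse as a structure: {exc}")

    # 3. displacement-ellipsoid elongation, in site order
    for site in sites:
        if site.label in config.excluded_labels:
            continue
        alert = adp_elongation_check(cell, site, config)
        if alert is not None:
            alerts.append(alert)

    # 4. bond-length plausibility against covalent-radius expectation
    graph = infer_bonds(cell, sites, DEFAULT_RADII, tol=config.bond_search_tol)
    for bond in graph.bonds:
        e1 = next(s.element for s in sites if s.label == bond.atom1)
        e2 = next(s.element for s in sites if s.label == bond.atom2)
        expected = DEFAULT_RADII[e1] + DEFAULT_RADII[e2]
        dev = bond.length - expected
        if abs(dev) > config.bond_dev_b:
            sev = "B"
        elif abs(dev) > config.bond_dev_c:
            sev = "C"
        else:
            continue
        pair = "-".join(sorted((bond.atom1, bond.atom2)))
        alerts.append(
            Alert(
                f"BOND01_ALERT_2_{sev}",
                sev,
                f"bond {pair} of {bond.length:.3f} A deviates "
                f"{dev:+.3f} A from the covalent-radius expectation {expected:.3f} A",
                pair,
                _EXPLANATIONS["BOND01"],
            )
        )

    # 5. occupancy sums over disorder assemblies
    assemblies: dict[str, dict[int, list[float]]] = {}
    for site in sites:
        if site.disorder_assembly is not None and site.disorder_group is not None:
            assemblies.setdefault(site.disorder_assembly, {}).setdefault(
                site.disorder_group, []
            ).append(site.occupancy)
    for asm in sorted(assemblies):
        groups = assemblies[asm]
        total = sum(np.mean(occs) for occs in groups.values())
        if abs(total - 1.0) > config.occupancy_tol:
            alerts.append(
                Alert(
                    "OCCU01_ALERT_2_B",
                    "B",
                    f"disorder assembly {asm}: group occupancies sum to "
                    f"{total:.3f}, not 1",
                    asm,
                    _EXPLANATIONS["OCCU01"],
                )
            )

    return ValidationReport(alerts=alerts)


def collect_responses(block: DataBlock) -> list[AlertResponse]:
    """Harvest ``_vrf_<CODE>`` items: author responses embedded in the CIF."""
    responses = []
    for tag, value in block.items():
        if tag.lower().startswith("_vrf_") and value.raw.strip():
            responses.append(AlertResponse(tag[5:], value.raw.strip()))
    return responses


def gate_submission(
    alerts: Sequence[Alert], responses: Sequence[AlertResponse]
) -> ValidationReport:
    """Apply the admission rule: every A/B alert needs a matching response.

    C alerts never block.  A response citing a code with no corresponding
    alert is recorded as a warning and ignored for gating.
    """
    report = ValidationReport(alerts=list(alerts), responses=list(responses))
    codes = {a.code.lower() for a in alerts}
    answered = set()
    for r in responses:
        if r.code.lower() not in codes:
            report.warnings.append(f"response cites unknown alert code {r.code}")
        else:
            answered.add(r.code.lower())
    report.admitted = all(a.code.lower() in answered for a in alerts if a.serious)
    return report


def render_report(report: ValidationReport, html: bool = False) -> str:
    """Render a validation report as stable plain text or minimal HTML.

    Each known alert code is anchored to its generic explanation; unknown
    codes are rendered without a link.
    """
    responses = {r.code.lower(): r for r in report.responses}
    if html:
        lines = ["<html><body><h1>Validation report</h1>"]
        if not report.alerts:
            lines.append("<p>No alerts.</p>")
        for a in report.alerts:
            prefix = a.code.split("_", 1)[0]
            if prefix in _EXPLANATIONS:
                code_html = f'<a href="#expl-{prefix}">{a.code}</a>'
            else:
                code_html = a.code
            lines.append(f"<p>{code_html} [{a.severity}] {a.message}</p>")
            r = responses.get(a.code.lower())
            if r is not None:
                lines.append(f"<blockquote>Author response: {r.text}</blockquote>")
        seen = []
        for a in report.alerts:
            prefix = a.code.split("_", 1)[0]
            if prefix in _EXPLANATIONS and prefix not in seen:
                seen.append(prefix)
                lines.append(f'<p id="expl-{prefix}"><em>{_EXPLANATIONS[prefix]}</em></p>')
        lines.append(f"<p>Admitted: {'yes' if report.admitted else 'no'}</p>")
        lines.append("</body></html>")
        return "\n".join(lines)
    lines = ["Validation report", "================="]
    if not report.alerts:
        lines.append("No alerts.")
    for a in report.alerts:
        lines.append(f"{a.code} [{a.severity}] {a.message}")
        if a.explanation:
            lines.append(f"    explanation: {a.explanation}")
        r = responses.get(a.code.lower())
        if r is not None:
            lines.append(f"    author response: {r.text}")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    lines.append(f"Admitted into review: {'yes' if report.admitted else 'no'}")
    return "\n".join(lines) + "\n"
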