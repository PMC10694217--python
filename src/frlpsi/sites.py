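"""Per-chlorophyll-site evidence integration and ancestral calls.

Each candidate chlorophyll-f site (B7, B37, B38, B30, A21, A23, B19) — plus
the A0B rotation of the electron-transfer chain — is supported by a small
set of residues playing one of three roles: ``hbond_donor`` (provides or
positions the H-bond to the C2 formyl or 13(1)-keto group), ``cavity``
(creates the steric room for the formyl substituent), and ``stabilizer``
(nearby group-specific residues that buttress the interaction).  The
ancestral call for a site is Y exactly when every donor and cavity residue
is group-specific and conserved in the reconstructed ancestor, and at least
``required_fraction`` of the stabilizers are; otherwise N.

Extant (per-structure) evidence is an input table; only the ancestral row
is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .specificity import ColumnClassification, ColumnStatus

ROLES = ("hbond_donor", "cavity", "stabilizer")


class SiteError(ValueError):
    pass


@dataclass(frozen=True)
class SupportingResidue:
    subunit: str
    column: int  # 1-based column in that subunit's alignment
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SiteError(f"unknown role '{self.role}'")


@dataclass
class SiteConfig:
    site_name: str
    residues: list[SupportingResidue]


@dataclass
class ChlSiteAssignment:
    site_name: str
    supporting_residues: list[SupportingResidue]
    extant_evidence: dict[str, str]  # structure_id -> Y/N
    ancestral_call: str  # Y/N
    rationale: str


def read_site_config(path: str | Path) -> list[SiteConfig]:
    """YAML site config: a list of {name, residues: [{subunit, column, role}]}."""
    data = yaml.safe_load(Path(path).read_text())
    sites = data["sites"] if isinstance(data, dict) else data
    out = []
    for entry in sites:
        residues = [
            SupportingResidue(r["subunit"], int(r["column"]), r["role"])
            for r in entry.get("residues", [])
        ]
        out.append(SiteConfig(site_name=entry["name"], residues=residues))
    return out


def read_evidence_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Structure-evidence TSV: header of site names, one row per structure."""
    lines = [
        l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    header = lines[0].split("\t")[1:]
    out: dict[str, dict[str, str]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        out[parts[0]] = dict(zip(header, parts[1:]))
    return out


def _resolve(
    site: SiteConfig,
    residue: SupportingResidue,
    classifications: dict[str, list[ColumnClassification]],
) -> ColumnClassification:
    cols = classifications.get(residue.subunit)
    if cols is None:
        raise SiteError(
            f"site {site.site_name}: no classification for subunit "
            f"'{residue.subunit}' (residue column {residue.column})"
        )
    for c in cols:
        if c.column == residue.column:
            return c
    raise SiteError(
        f"site {site.site_name}: column {residue.column} not classified "
        f"for subunit '{residue.subunit}'"
    )


def _is_conserved(c: ColumnClassification) -> bool:
    return c.status is ColumnStatus.GROUP_SPECIFIC and bool(c.ancestral_conserved)


def assign_ancestral_sites(
    site_configs: list[SiteConfig],
    classifications: dict[str, list[ColumnClassification]],
    evidence: dict[str, dict[str, str]] | None = None,
    required_fraction: float = 0.5,
) -> list[ChlSiteAssignment]:
    """Ancestral Y/N call per configured site.

    *classifications* maps subunit name to its (already ancestral-scored)
    column classifications; *evidence* optionally supplies per-structure
    extant Y/N observations to be carried into the output.
    """
    evidence = evidence or {}
    out = []
    for site in site_configs:
        extant = {
            sid: row.get(site.site_name, ".") for sid, row in evidence.items()
        }
        if not site.residues:
            out.append(
                ChlSiteAssignment(
                    site.site_name, [], extant, "N", "no evidence"
                )
            )
            continue
        required = [r for r in site.residues if r.role in ("hbond_donor", "cavity")]
        stabilizers = [r for r in site.residues if r.role == "stabilizer"]
        failures = []
        for r in required:
            c = _resolve(site, r, classifications)
            if not _is_conserved(c):
                state = c.ancestral_state or "?"
                failures.append(
                    f"{r.subunit}:{r.column} ({r.role}) not ancestral-conserved"
                    f" (status {c.status.value}, ancestral {state})"
                )
        n_stab_conserved = sum(
            _is_conserved(_resolve(site, r, classifications)) for r in stabilizers
        )
        stab_ok = (
            not stabilizers
            or n_stab_conserved / len(stabilizers) >= required_fraction
        )
        if not failures and stab_ok:
            call = "Y"
            rationale = (
                f"all {len(required)} donor/cavity residues ancestral-conserved"
                + (
                    f"; {n_stab_conserved}/{len(stabilizers)} stabilizers conserved"
                    if stabilizers
                    else ""
                )
            )
        else:
            call = "N"
            bits = failures[:]
            if not stab_ok:
                bits.append(
                    f"only {n_stab_conserved}/{len(stabilizers)} stabilizers conserved"
                )
            rationale = "; ".join(bits)
        out.append(
            ChlSiteAssignment(site.site_name, site.residues, extant, call, rationale)
        )
    return out


def write_site_matrix(
    assignments: list[ChlSiteAssignment],
    evidence: dict[str, dict[str, str]],
    path,
) -> None:
    """Write the structures-by-sites Y/N matrix with a final Ancestral row."""
    names = [a.site_name for a in assignments]
    with open(path, "w") as fh:
        fh.write("structure\t" + "\t".join(names) + "\n")
        for sid, row in evidence.items():
            fh.write(sid + "\t" + "\t".join(row.get(n, ".") for n in names) + "\n")
        fh.write("Ancestral\t" + "\t".join(a.ancestral_call for a in assignments) + "\n")
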