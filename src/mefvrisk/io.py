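"""Readers and writers for the package's text dialects and configs.

Formats:

* genotype tally TSV — header ``group_label  n_two_mut  n_het  n_none``,
  one tally per row;
* family TSV — a PED-inspired dialect, one individual per row with header
  ``family_id  individual_id  role  genotype  affected  diagnosis_retained``;
  genotypes are written ``mm|mN|NN`` (mutated/normal allele), ``affected``
  is ``1|0`` and ``diagnosis_retained`` is ``1|0|NA`` (NA for unaffected
  members, where the field is meaningless);
* populations YAML — list of per-population parameters (allele frequencies,
  observed prevalence ranges);
* risk scenario YAML — closed-population reconstruction inputs.

Lines starting with ``#`` are comments.  Parse errors carry the offending
line number.  Writers and readers round-trip exactly.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import yaml

from .carrier_excess import GenotypeTally
from .prevalence import ConfigError, PopulationParams
from .risk import PatientGenotypeFractions
from .siblings import FamilyMember, FamilyRecord

__all__ = [
    "ParseError",
    "load_family_tsv",
    "load_populations_yaml",
    "load_risk_scenarios_yaml",
    "load_tally_tsv",
    "packaged_fixture",
    "write_family_tsv",
    "write_tally_tsv",
]

TALLY_COLUMNS = ["group_label", "n_two_mut", "n_het", "n_none"]
FAMILY_COLUMNS = ["family_id", "individual_id", "role", "genotype", "affected", "diagnosis_retained"]
_GENOTYPE_TO_CODE = {"two_mut": "mm", "het": "mN", "none": "NN"}
_CODE_TO_GENOTYPE = {v: k for k, v in _GENOTYPE_TO_CODE.items()}


class ParseError(ValueError):
    """A malformed row in one of the package's text dialects."""

    def __init__(self, path: "Path | str", line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def packaged_fixture(name: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(resources.files("mefvrisk").joinpath("data", name))


def _read_rows(path: "Path | str", columns: list[str]):
    """Yield (line_number, row_dict) from a headered, #-commented TSV."""
    with open(path, newline="") as handle:
        header: list[str] | None = None
        for line_no, raw in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [cell.strip() for cell in raw]
                if header != columns:
                    raise ParseError(
                        path, line_no, f"expected header {columns}, got {header}"
                    )
                continue
            if len(raw) != len(columns):
                raise ParseError(
                    path, line_no, f"expected {len(columns)} fields, got {len(raw)}"
                )
            yield line_no, dict(zip(columns, (cell.strip() for cell in raw)))
    if header is None:
        raise ParseError(path, 1, "missing header line")


def _int_field(path, line_no, row, key) -> int:
    try:
        value = int(row[key])
    except ValueError:
        raise ParseError(path, line_no, f"{key} must be an integer, got {row[key]!r}") from None
    if value < 0:
        raise ParseError(path, line_no, f"{key} must be non-negative, got {value}")
    return value


def load_tally_tsv(path: "Path | str") -> list[GenotypeTally]:
    tallies = []
    for line_no, row in _read_rows(path, TALLY_COLUMNS):
        tallies.append(
            GenotypeTally(
                n_two_mut=_int_field(path, line_no, row, "n_two_mut"),
                n_het=_int_field(path, line_no, row, "n_het"),
                n_none=_int_field(path, line_no, row, "n_none"),
                group_label=row["group_label"],
            )
        )
    return tallies


def write_tally_tsv(tallies: list[GenotypeTally], path: "Path | str") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TALLY_COLUMNS)
        for tally in tallies:
            writer.writerow([tally.group_label, tally.n_two_mut, tally.n_het, tally.n_none])


def load_family_tsv(path: "Path | str") -> list[FamilyRecord]:
    members_by_family: dict[str, list[FamilyMember]] = {}
    for line_no, row in _read_rows(path, FAMILY_COLUMNS):
        genotype = _CODE_TO_GENOTYPE.get(row["genotype"])
        if genotype is None:
            raise ParseError(path, line_no, f"unknown genotype code {row['genotype']!r}")
        if row["affected"] not in ("0", "1"):
            raise ParseError(path, line_no, f"affected must be 0 or 1, got {row['affected']!r}")
        affected = row["affected"] == "1"
        retained_raw = row["diagnosis_retained"]
        if retained_raw == "NA":
            retained = None
        elif retained_raw in ("0", "1"):
            retained = retained_raw == "1"
        else:
            raise ParseError(
                path, line_no, f"diagnosis_retained must be 0, 1 or NA, got {retained_raw!r}"
            )
        try:
            member = FamilyMember(
                individual_id=row["individual_id"],
                role=row["role"],
                genotype=genotype,
                affected=affected,
                diagnosis_retained=retained,
            )
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from None
        members_by_family.setdefault(row["family_id"], []).append(member)
    families = []
    for family_id, members in members_by_family.items():
        try:
            families.append(FamilyRecord(family_id=family_id, members=members))
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from None
    return families


def write_family_tsv(families: list[FamilyRecord], path: "Path | str") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(FAMILY_COLUMNS)
        for family in families:
            for member in family.members:
                retained = "NA" if member.diagnosis_retained is None else int(member.diagnosis_retained)
                writer.writerow(
                    [
                        family.family_id,
                        member.individual_id,
                        member.role,
                        _GENOTYPE_TO_CODE[member.genotype],
                        int(member.affected),
                        retained,
                    ]
                )


def load_populations_yaml(path: "Path | str") -> list[PopulationParams]:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict) or "populations" not in payload:
        raise ConfigError(f"{path}: expected a mapping with a 'populations' list")
    populations = []
    for entry in payload["populations"]:
        if "q_strict" not in entry:
            raise ConfigError(f"{path}: population {entry.get('name', '?')!r} lacks q_strict")
        populations.append(
            PopulationParams(
                name=entry["name"],
                q_strict=float(entry["q_strict"]),
                q_inclusive=(
                    float(entry["q_inclusive"]) if entry.get("q_inclusive") is not None else None
                ),
                prevalence_observed_low=(
                    float(entry["prevalence_observed_low"])
                    if entry.get("prevalence_observed_low") is not None
                    else None
                ),
                prevalence_observed_high=(
                    float(entry["prevalence_observed_high"])
                    if entry.get("prevalence_observed_high") is not None
                    else None
                ),
                source_note=entry.get("source_note", ""),
            )
        )
    return populations


def load_risk_scenarios_yaml(path: "Path | str") -> list[dict]:
    """Risk scenario configs as dicts ready for ``build_risk_table``.

    Each scenario provides ``name``, ``q``, ``patient_fractions`` (list of
    three), ``population_size`` (default 100000), and either ``prevalence``
    or ``prevalence_list``.
    """
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict) or "scenarios" not in payload:
        raise ConfigError(f"{path}: expected a mapping with a 'scenarios' list")
    scenarios = []
    for entry in payload["scenarios"]:
        fractions = entry.get("patient_fractions")
        if not isinstance(fractions, list) or len(fractions) != 3:
            raise ConfigError(
                f"{path}: scenario {entry.get('name', '?')!r} needs patient_fractions "
                "with three entries"
            )
        if ("prevalence" in entry) == ("prevalence_list" in entry):
            raise ConfigError(
                f"{path}: scenario {entry.get('name', '?')!r} needs exactly one of "
                "'prevalence' or 'prevalence_list'"
            )
        scenarios.append(
            {
                "name": entry.get("name", ""),
                "q": float(entry["q"]),
                "fractions": PatientGenotypeFractions(*[float(f) for f in fractions]),
                "population_size": int(entry.get("population_size", 100_000)),
                "prevalence": entry.get("prevalence"),
                "prevalence_list": entry.get("prevalence_list"),
                "carrier_ratio_digits": int(entry.get("carrier_ratio_digits", 1)),
                "source_note": entry.get("source_note", ""),
            }
        )
    return scenarios
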