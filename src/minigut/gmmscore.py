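"""Gut metabolic module (GMM) machinery.

A module is an ordered list of reaction steps over KEGG orthologs (KOs).
Each step lists alternative routes separated by commas; within one
alternative, ``+`` joins KOs that are jointly required (an enzyme
complex). Scoring semantics:

* alternative abundance = min over its jointly required KOs
  (limiting-subunit rule);
* step abundance = sum over alternatives;
* module coverage = fraction of steps with nonzero abundance;
* module score = median (default estimator) over the covered steps;
* a module is *reported* for a unit when coverage >= ``coverage_cutoff``
  (default 0.5, inclusive) and the number of distinct observed KOs is
  >= ``min_kos`` (default 2). A KO's abundance is never split across
  modules: it counts fully in every module containing it.

File dialect
------------
``ID<TAB>Name`` header line, one step per line, ``///`` terminates the
module::

    MF_CELLO\tcellobiose degradation
    K02759+K02760+K02761
    K00702,K01223
    ///
"""

from __future__ import annotations

import statistics
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .iokit import KO_PATTERN, KOProfile, ParseError, ValidationError

__all__ = [
    "GMMDefinition",
    "ModuleScore",
    "parse_gmm_text",
    "read_gmm_definitions",
    "serialize_gmm_definitions",
    "write_gmm_definitions",
    "load_curated_modules",
    "cpm_normalize",
    "step_abundance",
    "score_module",
    "species_function_table",
]

Step = tuple[frozenset[str], ...]  # alternatives, each a set of required KOs


@dataclass(frozen=True)
class GMMDefinition:
    """One metabolic module: ordered steps of KO alternatives."""

    module_id: str
    name: str
    steps: tuple[Step, ...]

    def __post_init__(self) -> None:
        if not self.module_id:
            raise ValidationError("module id must be nonempty")
        steps = tuple(tuple(frozenset(alt) for alt in step) for step in self.steps)
        if len(steps) == 0:
            raise ValidationError(f"module {self.module_id!r} has no steps")
        for step in steps:
            if len(step) == 0:
                raise ValidationError(f"module {self.module_id!r}: empty step")
            for alt in step:
                if len(alt) == 0:
                    raise ValidationError(
                        f"module {self.module_id!r}: empty alternative"
                    )
                for ko in alt:
                    if not KO_PATTERN.match(ko):
                        raise ValidationError(
                            f"module {self.module_id!r}: malformed KO token {ko!r}"
                        )
        object.__setattr__(self, "steps", steps)

    @property
    def kos(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            for alt in step:
                out |= alt
        return frozenset(out)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ModuleScore:
    module_id: str
    unit_id: str
    score: float
    coverage: float
    n_observed_kos: int
    reported: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValidationError("coverage must be in [0, 1]")
        if self.score < 0:
            raise ValidationError("score must be >= 0")


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------


def _parse_step(line: str, lineno: int) -> Step:
    alternatives = []
    for alt_text in line.split(","):
        kos = frozenset(tok.strip() for tok in alt_text.split("+") if tok.strip())
        if not kos:
            raise ParseError(f"line {lineno}: empty alternative in step {line!r}")
        for ko in kos:
            if not KO_PATTERN.match(ko):
                raise ParseError(f"line {lineno}: no valid KO token in {ko!r}")
        alternatives.append(kos)
    if not alternatives:
        raise ParseError(f"line {lineno}: step line with no valid KO token")
    return tuple(alternatives)


def parse_gmm_text(text: str) -> list[GMMDefinition]:
    """Parse module definitions from text; see the module docstring for the dialect."""
    modules: list[GMMDefinition] = []
    seen: set[str] = set()
    current_header: tuple[str, str] | None = None
    current_steps: list[Step] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line == "" or line.startswith("#"):
            continue
        if current_header is None:
            if "\t" not in raw:
                raise ParseError(
                    f"line {lineno}: expected 'ID<TAB>Name' module header, got {line!r}"
                )
            module_id, _, name = raw.partition("\t")
            module_id, name = module_id.strip(), name.strip()
            if module_id in seen:
                raise ValidationError(f"line {lineno}: duplicate module id {module_id!r}")
            current_header = (module_id, name)
            current_steps = []
        elif line == "///":
            module_id, name = current_header
            if not current_steps:
                raise ParseError(f"line {lineno}: module {module_id!r} has no steps")
            modules.append(
                GMMDefinition(module_id=module_id, name=name, steps=tuple(current_steps))
            )
            seen.add(module_id)
            current_header = None
        else:
            current_steps.append(_parse_step(line, lineno))
    if current_header is not None:
        raise ParseError(f"module {current_header[0]!r} not terminated by '///'")
    return modules


def read_gmm_definitions(path) -> list[GMMDefinition]:
    with open(path) as fh:
        return parse_gmm_text(fh.read())


def serialize_gmm_definitions(modules: Iterable[GMMDefinition]) -> str:
    lines: list[str] = []
    for m in modules:
        lines.append(f"{m.module_id}\t{m.name}")
        for step in m.steps:
            lines.append(",".join("+".join(sorted(alt)) for alt in step))
        lines.append("///")
    return "\n".join(lines) + "\n"


def write_gmm_definitions(modules: Iterable[GMMDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_gmm_definitions(modules))


def load_curated_modules() -> list[GMMDefinition]:
    """Load the shipped curated-module fixtures.

    These mirror the curation intent of a diet-based minimal-microbiome
    design (cellobiose degradation, lactate consumption via electron
    bifurcation, 1,2-propanediol production routes, propionate production
    via 1,2-PD, and acetyl-CoA -> crotonyl-CoA as a butyrate-production
    proxy). KO contents are illustrative placeholders for testing the
    grammar and scoring machinery, not a curated reference set.
    """
    text = (
        resources.files("minigut.data").joinpath("curated_modules.txt").read_text()
    )
    return parse_gmm_text(text)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def cpm_normalize(counts: KOProfile) -> KOProfile:
    """Counts-per-million normalization: cpm(k) = count(k) / total * 1e6."""
    if counts.mode not in ("counts", "cpm"):
        raise ValidationError("cpm_normalize expects a counts-mode profile")
    total = float(sum(counts.kos.values()))
    if total <= 0:
        raise ValidationError(f"unit {counts.unit_id!r}: zero library size")
    return KOProfile(
        unit_id=counts.unit_id,
        kos={k: v / total * 1e6 for k, v in counts.kos.items()},
        mode="cpm",
    )


def step_abundance(step: Step, kos: KOProfile) -> float:
    """Sum over alternatives of the min over each alternative's required KOs."""
    total = 0.0
    for alt in step:
        total += min(kos.kos.get(ko, 0.0) for ko in alt)
    return total


_ESTIMATORS = ("median", "mean", "sum")


def score_module(
    module: GMMDefinition,
    kos: KOProfile,
    estimator: str = "median",
    coverage_cutoff: float = 0.5,
    min_kos: int = 2,
) -> ModuleScore:
    """Score one module for one unit.

    Coverage is the fraction of steps with nonzero abundance; the score is
    the estimator (default median; even step counts take the mean of the
    middle two) over the covered steps, 0 when no step is covered.
    """
    if estimator not in _ESTIMATORS:
        raise ValidationError(f"estimator must be one of {_ESTIMATORS}")
    abundances = [step_abundance(step, kos) for step in module.steps]
    covered = [a for a in abundances if a > 0]
    coverage = len(covered) / len(abundances)
    if not covered:
        score = 0.0
    elif estimator == "median":
        score = float(statistics.median(covered))
    elif estimator == "mean":
        score = float(sum(covered) / len(covered))
    else:
        score = float(sum(covered))
    observed = {ko for ko in module.kos if kos.kos.get(ko, 0.0) > 0}
    reported = coverage >= coverage_cutoff and len(observed) >= min_kos
    return ModuleScore(
        module_id=module.module_id,
        unit_id=kos.unit_id,
        score=score,
        coverage=coverage,
        n_observed_kos=len(observed),
        reported=reported,
    )


def species_function_table(
    profiles: Sequence[KOProfile],
    modules: Sequence[GMMDefinition],
    estimator: str = "median",
    coverage_cutoff: float = 0.5,
    min_kos: int = 2,
) -> pd.DataFrame:
    """Score every module for every unit; one row per unit x module.

    Counts-mode profiles are CPM-normalized first. Output rows are sorted
    by (unit_id, module_id) so the table is independent of input order.
    """
    if len(profiles) == 0 or len(modules) == 0:
        raise ValidationError("need at least one unit and one module")
    unit_ids = [p.unit_id for p in profiles]
    if len(set(unit_ids)) != len(unit_ids):
        raise ValidationError("duplicate unit ids in profiles")
    module_ids = [m.module_id for m in modules]
    if len(set(module_ids)) != len(module_ids):
        raise ValidationError("duplicate module ids")
    rows = []
    for profile in profiles:
        cpm = cpm_normalize(profile) if profile.mode == "counts" else profile
        for module in modules:
            ms = score_module(
                module,
                cpm,
                estimator=estimator,
                coverage_cutoff=coverage_cutoff,
                min_kos=min_kos,
            )
            rows.append(
                {
                    "unit_id": ms.unit_id,
                    "module_id": ms.module_id,
                    "module_name": module.name,
                    "score": ms.score,
                    "coverage": ms.coverage,
                    "n_observed_kos": ms.n_observed_kos,
                    "reported": ms.reported,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["unit_id", "module_id"], kind="mergesort").reset_index(
        drop=True
    )
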