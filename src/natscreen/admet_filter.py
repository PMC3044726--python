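"""Stage 1 of the screen: Lipinski rule-of-five with a configurable number
of allowed violations plus toxicophore substructure rejection.

Thresholds are inclusive (MW of exactly 500 Da is not a violation), the
common rule-of-five convention.  The shipped toxicophore SMARTS list is a
representative, user-replaceable set of reactive/promiscuous groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .chem_core import LipinskiDescriptors, Molecule, compute_descriptors


@dataclass(frozen=True)
class LipinskiThresholds:
    max_molecular_weight: float = 500.0
    max_logp: float = 5.0
    max_hbd: int = 5
    max_hba: int = 10


@dataclass
class ToxRule:
    rule_id: str
    smarts: str
    pattern: Chem.Mol = field(repr=False, default=None)


@dataclass
class AdmetDecision:
    passed: bool
    violation_count: int
    matched_toxicophores: list[str]

    def __post_init__(self) -> None:
        if not 0 <= self.violation_count <= 4:
            raise ValueError("violation count must be in 0..4")


def load_tox_rules(path: str | Path | None = None) -> list[ToxRule]:
    """Load a toxicophore rule file (``id<TAB>SMARTS`` per line).

    A malformed SMARTS is fatal at load time and reports the rule index.
    """
    if path is None:
        text = resources.files("natscreen.data").joinpath("tox_rules.smarts").read_text()
    else:
        text = Path(path).read_text()
    rules: list[ToxRule] = []
    index = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed toxicophore rule at index {index}: {line!r}")
        rule_id, smarts = parts
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise ValueError(f"invalid SMARTS in toxicophore rule {index} ({rule_id!r})")
        rules.append(ToxRule(rule_id=rule_id, smarts=smarts, pattern=pattern))
        index += 1
    return rules


def lipinski_violations(
    desc: LipinskiDescriptors, thresholds: LipinskiThresholds = LipinskiThresholds()
) -> int:
    """Number of rule-of-five threshold breaches (0-4), inclusive bounds."""
    return sum(
        [
            desc.molecular_weight > thresholds.max_molecular_weight,
            desc.logp > thresholds.max_logp,
            desc.hbd_count > thresholds.max_hbd,
            desc.hba_count > thresholds.max_hba,
        ]
    )


def admet_pass(
    mol: Molecule,
    max_violations: int = 1,
    tox_rules: list[ToxRule] | None = None,
    thresholds: LipinskiThresholds = LipinskiThresholds(),
) -> AdmetDecision:
    """Accept a molecule iff it breaches at most ``max_violations``
    rule-of-five thresholds and matches no toxicophore substructure."""
    if tox_rules is None:
        tox_rules = load_tox_rules()
    desc = compute_descriptors(mol)
    violations = lipinski_violations(desc, thresholds)
    query = Chem.RemoveHs(Chem.Mol(mol.rdmol))
    matched = [r.rule_id for r in tox_rules if query.HasSubstructMatch(r.pattern)]
    return AdmetDecision(
        passed=(violations <= max_violations and not matched),
        violation_count=violations,
        matched_toxicophores=matched,
    )
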