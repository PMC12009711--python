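"""Evaluation battery for generated molecule sets.

Metrics: validity (fraction parsing and sanitizing), uniqueness (distinct
canonical SMILES among valid), novelty (distinct valid canonical SMILES
absent from a canonicalized reference set), structural-alert pass rates for
the Glaxo, SureChEMBL and PAINS catalogs (fraction matching *no* alert —
higher is better), a property table (MW, Crippen LogP, QED,
Ertl–Schuffenhauer SA), and Bemis–Murcko scaffold diversity.

Filter fractions are computed over valid canonical-unique molecules.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.Chem.Scaffolds import MurckoScaffold

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (rdkit contrib, Ertl–Schuffenhauer SA score)

logger = logging.getLogger(__name__)

CATALOGS = {
    "Glaxo": FilterCatalogParams.FilterCatalogs.CHEMBL_Glaxo,
    "SureChEMBL": FilterCatalogParams.FilterCatalogs.CHEMBL_SureChEMBL,
    "PAINS": FilterCatalogParams.FilterCatalogs.PAINS,
}
DEFAULT_CATALOGS = ("Glaxo", "SureChEMBL", "PAINS")

_catalog_cache = {}


class MetricError(Exception):
    pass


def _get_catalog(name: str) -> FilterCatalog:
    if name not in CATALOGS:
        raise ValueError(f"unknown filter catalog {name!r}; "
                         f"known: {sorted(CATALOGS)}")
    if name not in _catalog_cache:
        params = FilterCatalogParams()
        params.AddCatalog(CATALOGS[name])
        _catalog_cache[name] = FilterCatalog(params)
    return _catalog_cache[name]


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES, or None if the input does not parse/sanitize."""
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _valid_canonical(smiles_list):
    return [c for c in (canonicalize(s) for s in smiles_list) if c is not None]


def validity(smiles_list) -> float:
    if not smiles_list:
        raise MetricError("validity of an empty list is undefined")
    return len(_valid_canonical(smiles_list)) / len(smiles_list)


def uniqueness(smiles_list) -> float:
    valid = _valid_canonical(smiles_list)
    if not valid:
        raise MetricError("uniqueness needs at least one valid molecule")
    return len(set(valid)) / len(valid)


def novelty(smiles_list, reference) -> float:
    """Fraction of distinct valid molecules absent from the reference set."""
    gen = set(_valid_canonical(smiles_list))
    if not gen:
        raise MetricError("novelty needs at least one valid molecule")
    ref = set(_valid_canonical(reference)) if reference else set()
    return len(gen - ref) / len(gen)


def passes_catalog(smiles: str, catalog_name: str) -> bool:
    """True when the molecule matches no alert in the named catalog."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return not _get_catalog(catalog_name).HasMatch(mol)


def filter_pass_rates(smiles_list, catalogs=DEFAULT_CATALOGS) -> dict:
    uniq = sorted(set(_valid_canonical(smiles_list)))
    if not uniq:
        raise MetricError("filter pass rates need at least one valid molecule")
    for name in catalogs:
        _get_catalog(name)  # raise early on unknown names
    return {name: float(np.mean([passes_catalog(s, name) for s in uniq]))
            for name in catalogs}


def sa_score(mol: Chem.Mol) -> float:
    return float(sascorer.calculateScore(mol))


def property_table(smiles_list) -> pd.DataFrame:
    """One row per valid molecule: MW (Da), Crippen LogP, QED, SA score."""
    rows = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.warning("skipping invalid SMILES %r in property table", s)
            continue
        rows.append({"smiles": Chem.MolToSmiles(mol),
                     "MW": float(Descriptors.MolWt(mol)),
                     "LogP": float(Crippen.MolLogP(mol)),
                     "QED": float(QED.qed(mol)),
                     "SA": sa_score(mol)})
    return pd.DataFrame(rows, columns=["smiles", "MW", "LogP", "QED", "SA"])


def scaffold_set(smiles_list):
    """Bemis–Murcko scaffolds and diversity ratio.

    Acyclic molecules reduce to the empty scaffold, which is counted once.
    Diversity = distinct scaffolds / number of valid molecules.
    """
    valid = _valid_canonical(smiles_list)
    if not valid:
        return set(), 0.0
    scaffolds = set()
    for s in valid:
        core = MurckoScaffold.GetScaffoldForMol(Chem.MolFromSmiles(s))
        scaffolds.add(Chem.MolToSmiles(core))
    return scaffolds, len(scaffolds) / len(valid)


@dataclass
class EvalReport:
    validity: float
    uniqueness: float
    novelty: float
    filter_pass: dict
    n_molecules: int
    n_valid: int
    scaffold_count: int
    scaffold_diversity: float
    scaffolds: list = field(default_factory=list)
    properties: pd.DataFrame | None = None

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d.pop("properties")
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"molecules            {self.n_molecules}",
            f"validity             {self.validity:.3f}",
            f"uniqueness           {self.uniqueness:.3f}",
            f"novelty              {self.novelty:.3f}",
        ]
        for k, v in self.filter_pass.items():
            lines.append(f"{k + ' pass':<21}{v:.3f}")
        lines.append(f"scaffold diversity   {self.scaffold_diversity:.3f} "
                     f"({self.scaffold_count} scaffolds)")
        if self.properties is not None and len(self.properties):
            med = self.properties[["MW", "LogP", "QED", "SA"]].median()
            lines.append("median MW/LogP/QED/SA  "
                         f"{med.MW:.1f} / {med.LogP:.2f} / {med.QED:.3f} / "
                         f"{med.SA:.2f}")
        return "\n".join(lines)


def evaluate_molecules(smiles_list, reference=(),
                       catalogs=DEFAULT_CATALOGS) -> EvalReport:
    valid = _valid_canonical(smiles_list)
    scaffolds, diversity = scaffold_set(smiles_list)
    return EvalReport(
        validity=validity(smiles_list),
        uniqueness=uniqueness(smiles_list),
        novelty=novelty(smiles_list, reference),
        filter_pass=filter_pass_rates(smiles_list, catalogs),
        n_molecules=len(smiles_list),
        n_valid=len(valid),
        scaffold_count=len(scaffolds),
        scaffold_diversity=diversity,
        scaffolds=sorted(scaffolds),
        properties=property_table(smiles_list),
    )
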