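"""Contingency-table statistics for substructure-ADR associations.

For a substructure pattern A and an ADR X over a drug set, the 2x2 table is
    a: A present, X positive      b: A absent, X positive
    c: A present, X negative      d: A absent, X negative
Association strength is the odds ratio (a*d)/(b*c) and significance the
Pearson chi-squared test with Yates continuity correction (df=1).  With
zero cells the odds ratio uses the Haldane-Anscombe +0.5 correction; the
chi-squared test is left uncorrected for zeros, and an empty margin gives
p = 1 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency, false_discovery_control, fisher_exact

from .chem_io import LabelMatrix, MoleculeGraph
from .interpret import SubstructureHit, smarts_to_query

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    a: int  # substructure+, ADR+
    b: int  # substructure-, ADR+
    c: int  # substructure+, ADR-
    d: int  # substructure-, ADR-
    haldane_corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SubstructureAssociation:
    smarts: str
    adr: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    significant: bool = False
    q_value: float | None = None
    hits: list[SubstructureHit] = field(default_factory=list)


def substructure_presence(molecules: list[MoleculeGraph], smarts: str) -> np.ndarray:
    """Boolean vector: does each molecule contain >= 1 match of the pattern."""
    q = smarts_to_query(smarts)
    return np.array([m.rdkit_mol().HasSubstructMatch(q) for m in molecules], dtype=bool)


def contingency(molecules: list[MoleculeGraph], smarts: str, y: np.ndarray) -> ContingencyTable:
    """Build the 2x2 table of pattern presence vs binary ADR labels."""
    y = np.asarray(y).astype(bool)
    if len(y) != len(molecules):
        raise ValueError(f"{len(molecules)} molecules vs {len(y)} labels")
    present = substructure_presence(molecules, smarts)
    return ContingencyTable(
        a=int(np.sum(present & y)),
        b=int(np.sum(~present & y)),
        c=int(np.sum(present & ~y)),
        d=int(np.sum(~present & ~y)),
    )


def odds_ratio(t: ContingencyTable) -> float:
    """(a*d)/(b*c); Haldane-Anscombe +0.5 applied to all cells if any is zero."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        t.haldane_corrected = True
    return (a * d) / (b * c)


def chi2_pvalue(t: ContingencyTable, yates: bool = True) -> float:
    """Two-sided upper-tail p of the Pearson chi-squared test, df=1.

    Yates continuity correction is on by default.  Empty row/column margins
    make the statistic undefined; p = 1 is returned with a warning.
    """
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.warning("zero margin in contingency table %s; p = 1", table.tolist())
        return 1.0
    return float(chi2_contingency(table, correction=yates).pvalue)


def fisher_pvalue(t: ContingencyTable) -> float:
    """Fisher's exact two-sided p (optional cross-check, not the default test)."""
    return float(fisher_exact([[t.a, t.b], [t.c, t.d]]).pvalue)


def assess_all(
    hits: list[SubstructureHit],
    molecules: list[MoleculeGraph],
    labels: LabelMatrix,
    alpha: float = 0.05,
    fdr: bool = False,
    yates: bool = True,
) -> list[SubstructureAssociation]:
    """Score every (unique SMARTS, ADR) pair.

    Each unique pattern among the hits is matched once against the molecule
    set; its presence vector is crossed with every ADR column.  Associations
    are flagged significant at raw p <= alpha, or at Benjamini-Hochberg
    q <= alpha when ``fdr`` is set.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not hits:
        return []
    by_smarts: dict[str, list[SubstructureHit]] = {}
    for h in hits:
        by_smarts.setdefault(h.smarts, []).append(h)

    mol_order = {m.mol_id: i for i, m in enumerate(molecules)}
    row_of = [mol_order[d] for d in labels.drugs if d in mol_order]
    if len(row_of) != len(labels.drugs):
        missing = set(labels.drugs) - set(mol_order)
        raise ValueError(f"{len(missing)} labeled drugs missing from molecule set, e.g. {sorted(missing)[:3]}")

    out: list[SubstructureAssociation] = []
    for smarts in sorted(by_smarts):
        present = substructure_presence(molecules, smarts)[row_of]
        for j, adr in enumerate(labels.adrs):
            y = labels.y[:, j].astype(bool)
            t = ContingencyTable(
                a=int(np.sum(present & y)), b=int(np.sum(~present & y)),
                c=int(np.sum(present & ~y)), d=int(np.sum(~present & ~y)),
            )
            out.append(
                SubstructureAssociation(
                    smarts=smarts, adr=adr, table=t,
                    odds_ratio=odds_ratio(t), p_value=chi2_pvalue(t, yates=yates),
                    hits=by_smarts[smarts],
                )
            )
    if fdr:
        q = false_discovery_control([assoc.p_value for assoc in out])
        for assoc, qv in zip(out, q):
            assoc.q_value = float(qv)
            assoc.significant = qv <= alpha
    else:
        for assoc in out:
            assoc.significant = assoc.p_value <= alpha
    return out


def associations_to_rows(assocs: list[SubstructureAssociation]) -> list[dict]:
    return [
        {
            "smarts": x.smarts, "adr": x.adr,
            "a": x.table.a, "b": x.table.b, "c": x.table.c, "d": x.table.d,
            "odds_ratio": x.odds_ratio, "p_value": x.p_value,
            "significant": x.significant,
            **({"q_value": x.q_value} if x.q_value is not None else {}),
        }
        for x in assocs
    ]
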