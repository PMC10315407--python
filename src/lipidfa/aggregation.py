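"""Within-class fatty-acid aggregation and lipid-class totals.

The analytic unit downstream of preprocessing is the within-class FA: for
each (lipid class, fatty acid) pair, the concentrations of all molecular
species of that class are summed, each weighted by how many chains of that
FA the molecule carries.  A DAG(16:0/16:0) therefore contributes twice its
concentration to DAG[16:0]; a DAG(16:0/14:0) contributes once to DAG[16:0]
and once to DAG[14:0].  For 1-chain classes the within-class FA equals the
species concentration.  Class totals are the plain unweighted sum of the
class's species.

A conservation law follows and is enforced in tests: per sample and class,
the within-class FAs sum to chains-per-molecule times the class total.
"""

from __future__ import annotations

import pandas as pd

from .nomenclature import LipidSpecies, parse_species, total_label, wcfa_label

__all__ = ["within_class_fa", "class_totals", "parse_panel"]


def parse_panel(columns) -> dict[str, LipidSpecies]:
    """Parse every species column name; raises on the first unparsable one."""
    return {name: parse_species(name) for name in columns}


def _require_imputed(values: pd.DataFrame) -> None:
    if values.isna().any().any():
        raise ValueError("matrix contains missing cells; filter and impute first")


def within_class_fa(values: pd.DataFrame) -> pd.DataFrame:
    """Multiplicity-weighted within-class FA concentrations.

    Parameters
    ----------
    values
        Imputed samples × species matrix; columns are shorthand names.

    Returns
    -------
    Samples × within-class-FA matrix with ``CLASS[C:D]`` columns.  Only
    (class, FA) pairs with at least one contributing species are emitted.
    """
    _require_imputed(values)
    panel = parse_panel(values.columns)
    contrib: dict[str, pd.Series] = {}
    for name, sp in panel.items():
        code = sp.lipid_class.code
        for fa in set(sp.chains):
            mult = sum(1 for c in sp.chains if c == fa)
            label = wcfa_label(code, fa)
            term = values[name] * mult
            contrib[label] = contrib[label] + term if label in contrib else term
    out = pd.DataFrame(contrib, index=values.index)
    # stable, readable ordering: class code then carbons then double bonds
    from .nomenclature import parse_wcfa_label

    def key(label: str):
        cls, fa = parse_wcfa_label(label)
        return (cls.code, fa.carbons, fa.double_bonds)

    return out[sorted(out.columns, key=key)]


def class_totals(values: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-class species sums, columns ``CLASS[total]``."""
    _require_imputed(values)
    panel = parse_panel(values.columns)
    totals: dict[str, pd.Series] = {}
    for name, sp in panel.items():
        label = total_label(sp.lipid_class.code)
        totals[label] = totals[label] + values[name] if label in totals else values[name].copy()
    out = pd.DataFrame(totals, index=values.index)
    return out[sorted(out.columns)]
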