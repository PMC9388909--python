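"""Hypergeometric over-representation analysis (ORA) of gene sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ConfigurationError, DataError

__all__ = ["GeneSetCollection", "read_gmt", "ora_hypergeometric"]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonised against a universe.

    Sets are intersected with the universe; sets that become empty are
    dropped with a warning.
    """

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def harmonized(self, universe: set) -> "GeneSetCollection":
        kept, desc = {}, {}
        for name, members in self.sets.items():
            inter = set(members) & universe
            if inter:
                kept[name] = inter
                desc[name] = self.descriptions.get(name, "")
            else:
                warnings.warn(f"gene set {name!r} empty after harmonization", stacklevel=2)
        return GeneSetCollection(kept, desc)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set] = {}
    desc: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name = parts[0]
        if name in sets:
            raise DataError(f"{path}:{ln}: duplicated gene set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
        desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def ora_hypergeometric(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    p = P(X >= k) where X counts query genes falling in the set when |query|
    genes are drawn without replacement from the universe containing |set|
    successes.  BH adjustment across sets; enrichment ratio =
    (k/|query|) / (|set|/|universe|).
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ConfigurationError("query gene set is empty")
    if not query <= universe:
        raise DataError(
            f"{len(query - universe)} query genes outside the universe "
            f"(e.g. {sorted(query - universe)[:5]})"
        )
    if not isinstance(collection, GeneSetCollection):
        collection = GeneSetCollection({k: set(v) for k, v in collection.items()})
    collection = collection.harmonized(universe)
    if not collection.sets:
        raise DataError("no gene sets overlap the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        n = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set": name,
                "set_size": n,
                "overlap": k,
                "expected": N * n / M,
                "enrichment_ratio": (k / N) / (n / M),
                "p": min(p, 1.0),
                "genes": ";".join(sorted(members & query)),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = bh_adjust(out["p"])
    return out.sort_values("p")
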