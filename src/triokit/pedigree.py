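"""Trio pedigrees and the population/group structure of the study design.

Five father-mother-offspring trios, one per population: Bateq (BTQ),
Mendriq (MDQ) and Semai (SMI) are Orang Asli (OA) groups from Peninsular
Malaysia; Dusun (DSN) and Murut (MRT) are North Bornean (NB) groups.
User-defined populations are allowed but must declare their group.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: Built-in population -> group mapping for the five study populations.
POPULATION_GROUPS: dict[str, str] = {
    "BTQ": "OA",
    "MDQ": "OA",
    "SMI": "OA",
    "DSN": "NB",
    "MRT": "NB",
}

#: Negrito subgroup used for NGO-CNV sharing classification.
NEGRITO_POPULATIONS = frozenset({"BTQ", "MDQ"})


@dataclass(frozen=True)
class TrioPedigree:
    """Sample identities and roles for one father-mother-offspring trio."""

    trio_id: str
    father_id: str
    mother_id: str
    offspring_id: str
    population: str
    group: str | None = None

    def __post_init__(self) -> None:
        ids = {self.father_id, self.mother_id, self.offspring_id}
        if len(ids) != 3:
            raise ValueError(f"trio {self.trio_id}: sample ids must be distinct, got {ids}")
        grp = self.group if self.group is not None else POPULATION_GROUPS.get(self.population)
        if grp is None:
            raise ValueError(
                f"trio {self.trio_id}: population {self.population!r} has no known "
                "group; pass group='OA' or 'NB' (or a custom label) explicitly"
            )
        object.__setattr__(self, "group", grp)

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        """(father, mother, offspring) in that fixed order."""
        return (self.father_id, self.mother_id, self.offspring_id)


def read_ped(path: str | Path, populations: dict[str, str] | None = None) -> list[TrioPedigree]:
    """Read trios from a 6-column PED file.

    The family id doubles as the trio id and, when it matches a known
    population code, the population label; ``populations`` may map family id
    to population explicitly. Rows with both parents set to 0 are founders;
    the offspring row (non-zero father and mother) anchors each trio.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    trios: list[TrioPedigree] = []
    for fid, fam in df.groupby("fid", sort=False):
        offspring = fam[(fam.father != "0") & (fam.mother != "0")]
        if len(offspring) != 1:
            raise ValueError(f"family {fid}: expected exactly one offspring row, got {len(offspring)}")
        child = offspring.iloc[0]
        pop = (populations or {}).get(fid, fid)
        trios.append(
            TrioPedigree(
                trio_id=str(fid),
                father_id=str(child.father),
                mother_id=str(child.mother),
                offspring_id=str(child.iid),
                population=pop,
                group=POPULATION_GROUPS.get(pop),
            )
        )
    return trios


def write_ped(trios: list[TrioPedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.trio_id}\t{t.father_id}\t0\t0\t1\t-9\n")
            fh.write(f"{t.trio_id}\t{t.mother_id}\t0\t0\t2\t-9\n")
            fh.write(f"{t.trio_id}\t{t.offspring_id}\t{t.father_id}\t{t.mother_id}\t0\t-9\n")
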