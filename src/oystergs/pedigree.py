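"""Pedigree container shared by the simulator, A-matrix and BLUP stages.

A pedigree is a table of (id, sire, dam, generation) records with 0 coding
an unknown parent.  Ids are integers assigned in birth order; parents always
precede offspring after :meth:`Pedigree.sorted`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Pedigree:
    df: pd.DataFrame  # columns: id, sire, dam, generation

    def __post_init__(self):
        required = {"id", "sire", "dam", "generation"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        self.df = self.df[["id", "sire", "dam", "generation"]].astype(int).reset_index(drop=True)
        ids = set(self.df["id"])
        if len(ids) != len(self.df):
            raise ValueError("duplicate ids in pedigree")
        for col in ("sire", "dam"):
            unknown = set(self.df[col]) - ids - {0}
            if unknown:
                raise ValueError(f"{col} ids not in pedigree: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def founders(self) -> np.ndarray:
        d = self.df
        return d.loc[(d.sire == 0) & (d.dam == 0), "id"].to_numpy()

    def generation(self, g: int) -> np.ndarray:
        return self.df.loc[self.df.generation == g, "id"].to_numpy()

    def families(self, generation: int | None = None) -> dict:
        """Map (sire, dam) -> list of offspring ids, for known-parent records."""
        d = self.df[(self.df.sire != 0) & (self.df.dam != 0)]
        if generation is not None:
            d = d[d.generation == generation]
        fams: dict = {}
        for row in d.itertuples(index=False):
            fams.setdefault((row.sire, row.dam), []).append(row.id)
        return fams

    def sorted(self) -> "Pedigree":
        """Topologically sort so every parent precedes its offspring.

        Raises on a pedigree loop, naming an id in the cycle.
        """
        d = self.df
        parents = dict(zip(d.id, zip(d.sire, d.dam)))
        order: list[int] = []
        state: dict[int, int] = {}  # 0 unseen / 1 in progress / 2 done

        for start in d["id"]:
            if state.get(start, 0) == 2:
                continue
            stack = [start]
            while stack:
                node = stack[-1]
                if state.get(node, 0) == 2:
                    stack.pop()
                    continue
                state[node] = 1
                pending = []
                for p in parents.get(node, (0, 0)):
                    if p == 0:
                        continue
                    s = state.get(p, 0)
                    if s == 1 and p in stack:
                        raise ValueError(f"pedigree loop involving id {p}")
                    if s != 2:
                        pending.append(p)
                if pending:
                    stack.extend(pending)
                else:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        idx = d.set_index("id").loc[order].reset_index()
        return Pedigree(idx)

    def write(self, path) -> None:
        """Write as 4-column whitespace-separated text with a header."""
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep=r"\s+"))
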