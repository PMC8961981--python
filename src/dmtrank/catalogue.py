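"""Disease-modifying-therapy (DMT) catalogue.

The catalogue fixes the set of therapies the models rank and classifies each
as first- or second-line. Line classification is registry policy, not a model
output, so it lives in a user-editable JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator


class CatalogueError(KeyError):
    """Unknown DMT identifier."""


@dataclass(frozen=True)
class DMTEntry:
    id: str
    name: str
    line: int  # 1 = first line, 2 = second line / high efficacy

    def __post_init__(self):
        if self.line not in (1, 2):
            raise ValueError(f"line must be 1 or 2, got {self.line!r}")


class DMTCatalogue:
    """Ordered collection of :class:`DMTEntry`, unique by id."""

    def __init__(self, entries: list[DMTEntry]):
        if not entries:
            raise ValueError("catalogue must contain at least one DMT")
        ids = [e.id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate DMT ids in catalogue")
        self._entries = list(entries)
        self._by_id = {e.id: e for e in entries}

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[DMTEntry]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, dmt_id: str) -> bool:
        return dmt_id in self._by_id

    def __getitem__(self, dmt_id: str) -> DMTEntry:
        try:
            return self._by_id[dmt_id]
        except KeyError:
            raise CatalogueError(
                f"unknown DMT {dmt_id!r}; catalogue has {sorted(self._by_id)}"
            ) from None

    def __eq__(self, other) -> bool:
        return isinstance(other, DMTCatalogue) and self._entries == other._entries

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self._entries]

    def is_second_line(self, dmt_id: str) -> bool:
        return self[dmt_id].line == 2

    # -- IO -----------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [{"id": e.id, "name": e.name, "line": e.line} for e in self]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DMTCatalogue":
        payload = json.loads(Path(path).read_text())
        return cls([DMTEntry(d["id"], d["name"], int(d["line"])) for d in payload])


def default_catalogue() -> DMTCatalogue:
    """Six-therapy catalogue spanning the common RRMS platform and
    high-efficacy options."""
    return DMTCatalogue(
        [
            DMTEntry("interferon_beta", "Interferon beta", 1),
            DMTEntry("glatiramer_acetate", "Glatiramer acetate", 1),
            DMTEntry("dimethyl_fumarate", "Dimethyl fumarate", 1),
            DMTEntry("teriflunomide", "Teriflunomide", 1),
            DMTEntry("fingolimod", "Fingolimod", 2),
            DMTEntry("natalizumab", "Natalizumab", 2),
        ]
    )
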