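"""Static holozoan clade hierarchy used for presence/absence summaries.

The hierarchy encodes the consensus clustering of phyla within Holozoa:
Holozoa splits into Teretosporea (Corallochytrea + Ichthyosporea) and
Filozoa; Filozoa into Filasterea and Choanozoa; Choanozoa into
Choanoflagellata and Metazoa; Metazoa assembles Ctenophora, Porifera,
Placozoa, Cnidaria and Bilateria, the latter dividing into Xenacoelomorpha
and Nephrozoa (Deuterostomia + Protostomia) down to the sampled phyla.
Chordata is resolved into its subphyla (Vertebrata, Tunicata,
Cephalochordata). Labels outside this tree (e.g. Bacteria, Fungi) are
treated as non-holozoan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_EDGES = [
    ("Holozoa", "Teretosporea"),
    ("Holozoa", "Filozoa"),
    ("Teretosporea", "Corallochytrea"),
    ("Teretosporea", "Ichthyosporea"),
    ("Filozoa", "Filasterea"),
    ("Filozoa", "Choanozoa"),
    ("Choanozoa", "Choanoflagellata"),
    ("Choanozoa", "Metazoa"),
    ("Metazoa", "Ctenophora"),
    ("Metazoa", "Porifera"),
    ("Metazoa", "Placozoa"),
    ("Metazoa", "Cnidaria"),
    ("Metazoa", "Bilateria"),
    ("Bilateria", "Xenacoelomorpha"),
    ("Bilateria", "Nephrozoa"),
    ("Nephrozoa", "Deuterostomia"),
    ("Nephrozoa", "Protostomia"),
    ("Deuterostomia", "Chordata"),
    ("Deuterostomia", "Ambulacraria"),
    ("Ambulacraria", "Echinodermata"),
    ("Ambulacraria", "Hemichordata"),
    ("Chordata", "Vertebrata"),
    ("Chordata", "Tunicata"),
    ("Chordata", "Cephalochordata"),
    ("Protostomia", "Ecdysozoa"),
    ("Protostomia", "Lophotrochozoa"),
    ("Ecdysozoa", "Panarthropoda"),
    ("Ecdysozoa", "Scalidophora"),
    ("Ecdysozoa", "Nematoida"),
    ("Panarthropoda", "Arthropoda"),
    ("Panarthropoda", "Tardigrada"),
    ("Panarthropoda", "Onychophora"),
    ("Scalidophora", "Priapulida"),
    ("Scalidophora", "Kinorhyncha"),
    ("Scalidophora", "Loricifera"),
    ("Nematoida", "Nematoda"),
    ("Nematoida", "Nematomorpha"),
    ("Lophotrochozoa", "Annelida"),
    ("Lophotrochozoa", "Bryozoa"),
    ("Lophotrochozoa", "Brachiopoda"),
    ("Lophotrochozoa", "Mollusca"),
    ("Lophotrochozoa", "Platyhelminthes"),
    ("Lophotrochozoa", "Rotifera"),
]


@dataclass(frozen=True)
class CladeTaxonomy:
    """A rooted clade hierarchy as parent->child edges (a tree, unique names)."""

    edges: tuple = tuple(_EDGES)
    parent: dict = field(default=None, compare=False)

    def __post_init__(self):
        parent: dict = {}
        for p, c in self.edges:
            if c in parent:
                raise ValueError(f"duplicate clade name {c!r}")
            parent[c] = p
        roots = {p for p, _ in self.edges} - set(parent)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have a single root, got {sorted(roots)}")
        # cycle check: walking up from any node must terminate
        for c in parent:
            seen = set()
            node = c
            while node in parent:
                if node in seen:
                    raise ValueError("taxonomy contains a cycle")
                seen.add(node)
                node = parent[node]
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "_root", roots.pop())

    @property
    def root(self) -> str:
        return self._root

    def __contains__(self, name: str) -> bool:
        return name == self.root or name in self.parent

    def lineage(self, name: str) -> list:
        """Path from *name* up to the root, inclusive; [] if unknown."""
        if name not in self:
            return []
        path = [name]
        while path[-1] in self.parent:
            path.append(self.parent[path[-1]])
        return path

    def is_under(self, name: str, ancestor: str) -> bool:
        """True iff *name* is *ancestor* or a descendant of it."""
        return ancestor in self.lineage(name)

    def is_holozoan(self, name: str) -> bool:
        return self.is_under(name, "Holozoa")


DEFAULT_TAXONOMY = CladeTaxonomy()
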