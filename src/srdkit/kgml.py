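"""Parse, merge and write KGML (KEGG Markup Language) pathway documents.

KGML is the XML schema KEGG serves for its pathway maps.  The subset modelled
here is the part needed to build reaction graphs: ``entry`` elements (compounds,
genes, map links) and ``reaction`` elements (substrates, products).  Catalysis
is encoded KGML-style: a gene entry's ``reaction`` attribute names the
reaction(s) it catalyzes.

Entries of unrecognized KGML types (``ortholog``, ``group``, ``enzyme`` ...)
are retained with kind ``other`` and excluded from graph construction.
Glycan identifiers (``gl:``) count as compounds since they are nodes of KEGG
maps.
"""

from __future__ import annotations

import datetime
import json
import urllib.error
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Entry",
    "Reaction",
    "PathwayDocument",
    "KgmlError",
    "KgmlParseError",
    "KgmlValidationError",
    "KgmlFetchError",
    "parse_kgml",
    "write_kgml",
    "merge_pathways",
    "fetch_pathway",
    "canonical_form",
]

KEGG_REST_URL = "https://rest.kegg.jp"

COMPOUND = "compound"
GENE = "gene"
MAP = "map"
OTHER = "other"

_KGML_KIND = {"compound": COMPOUND, "gene": GENE, "map": MAP}


class KgmlError(Exception):
    """Base class for KGML model errors."""


class KgmlParseError(KgmlError):
    """Raised for malformed XML; carries the offending line when known."""


class KgmlValidationError(KgmlError):
    """Raised when a document violates the model invariants.

    ``problems`` lists every violation found, e.g. dangling entry references.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class KgmlFetchError(KgmlError):
    """Raised when a pathway cannot be retrieved (offline, HTTP failure)."""


@dataclass(frozen=True)
class Entry:
    """A KGML ``entry``: a document-local node of the pathway map.

    ``kegg_ids`` may hold several identifiers — KGML encodes e.g. an isoenzyme
    family as one gene entry whose ``name`` lists several ``hsa:`` IDs, all of
    which catalyze the entry's reactions.
    """

    entry_id: str
    kind: str
    kegg_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind in (COMPOUND, GENE) and not self.kegg_ids:
            raise KgmlValidationError(
                [f"entry {self.entry_id!r} of kind {self.kind!r} has no KEGG IDs"]
            )


@dataclass(frozen=True)
class Reaction:
    """One enzymatic reaction: substrates -> products, catalyzed by genes.

    ``substrates``/``products``/``catalysts`` are entry IDs, resolved against
    the owning document.  ``catalysts`` may be empty (spontaneous reaction):
    such a reaction still connects its compounds but labels no gene.
    """

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    catalysts: tuple[str, ...] = ()
    reversible: bool = True

    def __post_init__(self) -> None:
        problems = []
        if not self.substrates:
            problems.append(f"reaction {self.reaction_id!r} has no substrates")
        if not self.products:
            problems.append(f"reaction {self.reaction_id!r} has no products")
        if problems:
            raise KgmlValidationError(problems)


@dataclass
class PathwayDocument:
    """In-memory model of one (possibly merged) KGML pathway."""

    pathway_id: str
    title: str = ""
    entries: tuple[Entry, ...] = ()
    reactions: tuple[Reaction, ...] = ()
    _by_id: dict[str, Entry] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise KgmlValidationError(["pathway_id must be non-empty"])
        self.entries = tuple(self.entries)
        self.reactions = tuple(self.reactions)
        self._by_id = {e.entry_id: e for e in self.entries}
        self.validate()

    def entry(self, entry_id: str) -> Entry:
        return self._by_id[entry_id]

    def compound_entries(self) -> list[Entry]:
        return [e for e in self.entries if e.kind == COMPOUND]

    def gene_entries(self) -> list[Entry]:
        return [e for e in self.entries if e.kind == GENE]

    def validate(self) -> None:
        """Check reference integrity; raise with the full problem list."""
        problems: list[str] = []
        for r in self.reactions:
            for role, refs, want in (
                ("substrate", r.substrates, COMPOUND),
                ("product", r.products, COMPOUND),
                ("catalyst", r.catalysts, GENE),
            ):
                for ref in refs:
                    e = self._by_id.get(ref)
                    if e is None:
                        problems.append(
                            f"reaction {r.reaction_id!r}: dangling {role} "
                            f"reference {ref!r}"
                        )
                    elif e.kind != want:
                        problems.append(
                            f"reaction {r.reaction_id!r}: {role} {ref!r} is "
                            f"kind {e.kind!r}, expected {want!r}"
                        )
        if problems:
            raise KgmlValidationError(problems)


def _entry_kind(kgml_type: str, names: Sequence[str]) -> str:
    if kgml_type == "compound" or any(n.startswith("gl:") for n in names):
        return COMPOUND
    return _KGML_KIND.get(kgml_type, OTHER)


def parse_kgml(xml_text: str) -> PathwayDocument:
    """Parse KGML text into a :class:`PathwayDocument`.

    Raises :class:`KgmlParseError` on malformed XML (naming the line) and
    :class:`KgmlValidationError` when a reaction references an undeclared
    entry — dangling references are reported, never silently dropped.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:  # exc.position is (line, column)
        line = exc.position[0] if exc.position else "?"
        raise KgmlParseError(f"malformed KGML at line {line}: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"root element is {root.tag!r}, expected 'pathway'")

    pathway_id = (root.get("name") or "").removeprefix("path:") or root.get("number", "")
    title = root.get("title", "")

    entries: list[Entry] = []
    catalysis: dict[str, list[str]] = {}  # reaction name -> gene entry ids
    for el in root.findall("entry"):
        names = tuple((el.get("name") or "").split())
        kind = _entry_kind(el.get("type", ""), names)
        entry = Entry(entry_id=el.get("id", ""), kind=kind, kegg_ids=names)
        entries.append(entry)
        if kind == GENE:
            for rxn_name in (el.get("reaction") or "").split():
                catalysis.setdefault(rxn_name, []).append(entry.entry_id)

    reactions: list[Reaction] = []
    for el in root.findall("reaction"):
        name = el.get("name", "")
        rid = name.split()[0].removeprefix("rn:") if name else el.get("id", "")
        subs = tuple(s.get("id", "") for s in el.findall("substrate"))
        prods = tuple(p.get("id", "") for p in el.findall("product"))
        cats: list[str] = []
        for token in name.split():
            cats.extend(catalysis.get(token, []))
        reactions.append(
            Reaction(
                reaction_id=rid,
                substrates=subs,
                products=prods,
                catalysts=tuple(dict.fromkeys(cats)),
                reversible=el.get("type", "reversible") == "reversible",
            )
        )
    return PathwayDocument(
        pathway_id=pathway_id, title=title, entries=tuple(entries), reactions=tuple(reactions)
    )


def write_kgml(doc: PathwayDocument) -> str:
    """Serialize a document to KGML text that :func:`parse_kgml` round-trips."""
    doc.validate()
    root = ET.Element(
        "pathway",
        name=f"path:{doc.pathway_id}",
        title=doc.title,
        number=doc.pathway_id.lstrip("abcdefghijklmnopqrstuvwxyz"),
    )
    # gene entry -> reactions it catalyzes (KGML's catalysis encoding)
    catalyzes: dict[str, list[str]] = {}
    for r in doc.reactions:
        for gid in r.catalysts:
            catalyzes.setdefault(gid, []).append(f"rn:{r.reaction_id}")
    kgml_type = {COMPOUND: "compound", GENE: "gene", MAP: "map", OTHER: "other"}
    for e in doc.entries:
        attrs = {"id": e.entry_id, "name": " ".join(e.kegg_ids), "type": kgml_type[e.kind]}
        if e.entry_id in catalyzes:
            attrs["reaction"] = " ".join(catalyzes[e.entry_id])
        ET.SubElement(root, "entry", attrs)
    for r in doc.reactions:
        rel = ET.SubElement(
            root,
            "reaction",
            id=r.reaction_id,
            name=f"rn:{r.reaction_id}",
            type="reversible" if r.reversible else "irreversible",
        )
        for sid in r.substrates:
            ET.SubElement(rel, "substrate", id=sid, name=doc.entry(sid).kegg_ids[0])
        for pid in r.products:
            ET.SubElement(rel, "product", id=pid, name=doc.entry(pid).kegg_ids[0])
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def canonical_form(doc: PathwayDocument):
    """A hashable normal form: equal documents have equal canonical forms.

    Entry identity is (kind, KEGG IDs); reaction identity additionally resolves
    entry references to KEGG IDs, so documents differing only in local entry
    numbering or element order compare equal.
    """

    def ids(refs: Iterable[str]) -> tuple[str, ...]:
        out: set[str] = set()
        for ref in refs:
            out.update(doc.entry(ref).kegg_ids)
        return tuple(sorted(out))

    entry_keys = tuple(sorted({(e.kind, tuple(sorted(e.kegg_ids))) for e in doc.entries}))
    reaction_keys = tuple(
        sorted(
            {
                (r.reaction_id, ids(r.substrates), ids(r.products), ids(r.catalysts), r.reversible)
                for r in doc.reactions
            }
        )
    )
    return (doc.pathway_id, doc.title, entry_keys, reaction_keys)


def merge_pathways(docs: Sequence[PathwayDocument]) -> PathwayDocument:
    """Union of several pathway documents.

    Entries are deduplicated by (kind, KEGG ID set); reactions by reaction ID
    plus reactant KEGG ID sets.  The merged pathway ID joins the inputs with
    ``+`` — KEGG itself has no ID for ad-hoc graph unions.
    """
    if not docs:
        raise ValueError("merge_pathways requires at least one document")
    if len(docs) == 1:
        return docs[0]

    entry_ids: dict[tuple, str] = {}  # (kind, kegg ids) -> merged entry id
    entries: list[Entry] = []

    def merged_entry(e: Entry) -> str:
        key = (e.kind, tuple(sorted(e.kegg_ids)))
        if key not in entry_ids:
            new_id = str(len(entry_ids) + 1)
            entry_ids[key] = new_id
            entries.append(Entry(entry_id=new_id, kind=e.kind, kegg_ids=e.kegg_ids))
        return entry_ids[key]

    seen_reactions: set[tuple] = set()
    reactions: list[Reaction] = []
    for doc in docs:
        remap = {e.entry_id: merged_entry(e) for e in doc.entries}
        for r in doc.reactions:
            subs = tuple(sorted({remap[s] for s in r.substrates}))
            prods = tuple(sorted({remap[p] for p in r.products}))
            key = (r.reaction_id, subs, prods)
            if key in seen_reactions:
                continue
            seen_reactions.add(key)
            reactions.append(
                Reaction(
                    reaction_id=r.reaction_id,
                    substrates=subs,
                    products=prods,
                    catalysts=tuple(sorted({remap[c] for c in r.catalysts})),
                    reversible=r.reversible,
                )
            )
    merged_id = "+".join(dict.fromkeys(d.pathway_id for d in docs))
    title = "; ".join(t for t in dict.fromkeys(d.title for d in docs) if t)
    return PathwayDocument(
        pathway_id=merged_id, title=title, entries=tuple(entries), reactions=tuple(reactions)
    )


def fetch_pathway(
    pathway_id: str,
    cache_dir: str | Path,
    base_url: str = KEGG_REST_URL,
    timeout: float = 30.0,
) -> str:
    """Cache-first retrieval of a pathway's KGML from the KEGG REST API.

    Always serves from ``cache_dir/<pathway_id>.xml`` when present; otherwise
    downloads ``<base_url>/get/<pathway_id>/kgml``, stores the text plus a
    JSON sidecar recording the retrieval date and URL (KEGG map content drifts
    across releases, so the date is part of the provenance), and returns it.

    Raises :class:`KgmlFetchError` with the HTTP status on failure, or an
    explicit offline message when no cache exists and the network is down.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached = cache_dir / f"{pathway_id}.xml"
    if cached.exists():
        return cached.read_text()
    url = f"{base_url}/get/{pathway_id}/kgml"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8")
    except urllib.error.HTTPError as exc:
        raise KgmlFetchError(f"HTTP {exc.code} fetching {url}") from exc
    except (urllib.error.URLError, OSError) as exc:
        raise KgmlFetchError(
            f"no cached copy of {pathway_id!r} in {cache_dir} and the network "
            f"is unreachable ({exc})"
        ) from exc
    cached.write_text(text)
    meta = {
        "pathway_id": pathway_id,
        "url": url,
        "retrieved": datetime.date.today().isoformat(),
    }
    (cache_dir / f"{pathway_id}.meta.json").write_text(json.dumps(meta, indent=1))
    return text
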