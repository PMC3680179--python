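"""Corpus-directory and manifest I/O.

A corpus set on disk is a directory per corpus holding one ``.txt`` /
``.a1`` / ``.a2`` triple (plus an optional ``.conll`` parse layer) per
document and a ``splits.tsv`` file, tied together by a YAML manifest:

.. code-block:: yaml

    corpora:
      - name: A
        dir: A
        splits: A/splits.tsv
        normalization:            # optional
          event_type_map: {Catalysis: Positive_regulation}
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .corpus import Corpus, NormalizationRules, normalize_corpus
from .standoff import read_document, read_parse_layer, write_document, \
    write_parse_layer
from .synthetic import ScenarioConfig


def write_corpora(corpora: list[Corpus], out_dir: str | Path,
                  scenario: Optional[ScenarioConfig] = None) -> Path:
    """Write corpus directories plus the manifest; returns the manifest
    path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"corpora": []}
    for corpus in corpora:
        cdir = out / corpus.name
        cdir.mkdir(exist_ok=True)
        split_lines = []
        for doc_id in sorted(corpus.documents):
            doc = corpus.documents[doc_id]
            (cdir / f"{doc_id}.txt").write_text(doc.text)
            a1, a2 = write_document(doc)
            (cdir / f"{doc_id}.a1").write_text(a1)
            (cdir / f"{doc_id}.a2").write_text(a2)
            if doc.tokens is not None:
                (cdir / f"{doc_id}.conll").write_text(
                    write_parse_layer(doc))
            split_lines.append(f"{doc_id}\t{corpus.splits[doc_id]}")
        (cdir / "splits.tsv").write_text("\n".join(split_lines) + "\n")
        manifest["corpora"].append({
            "name": corpus.name,
            "dir": corpus.name,
            "splits": f"{corpus.name}/splits.tsv",
        })
    if scenario is not None:
        manifest["scenario"] = scenario.name
        manifest["seed"] = scenario.seed
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_corpus_dir(cdir: str | Path, name: str,
                    splits_file: Optional[str | Path] = None) -> Corpus:
    """Load one corpus directory (every ``*.txt`` with its sidecars)."""
    cdir = Path(cdir)
    corpus = Corpus(name=name)
    split_of: dict[str, str] = {}
    if splits_file is not None and Path(splits_file).exists():
        for line in Path(splits_file).read_text().splitlines():
            if line.strip():
                doc_id, split = line.split("\t")
                split_of[doc_id] = split
    for txt in sorted(cdir.glob("*.txt")):
        doc_id = txt.stem
        a1 = cdir / f"{doc_id}.a1"
        a2 = cdir / f"{doc_id}.a2"
        doc = read_document(
            doc_id, txt.read_text(),
            a1.read_text() if a1.exists() else "",
            a2.read_text() if a2.exists() else "")
        conll = cdir / f"{doc_id}.conll"
        if conll.exists():
            read_parse_layer(doc, conll.read_text())
        corpus.add(doc, split_of.get(doc_id, "train"))
    return corpus


def load_manifest(manifest_path: str | Path) -> list[Corpus]:
    """Load a corpus set, applying any per-corpus normalization rules."""
    mpath = Path(manifest_path)
    root = mpath.parent
    spec = yaml.safe_load(mpath.read_text())
    corpora = []
    for entry in spec["corpora"]:
        corpus = read_corpus_dir(root / entry["dir"], entry["name"],
                                 root / entry["splits"]
                                 if "splits" in entry else None)
        if entry.get("normalization"):
            rules = NormalizationRules.from_dict(entry["normalization"])
            corpus = normalize_corpus(corpus, rules)
        corpora.append(corpus)
    return corpora
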