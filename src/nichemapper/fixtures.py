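"""Bundled reference fixture: the published receptor-curation worked example.

The packaged data directory carries the 16-gene cell-surface misannotation
blacklist and the two published exclusion lists (receptors with no known
ligand: MR1, TMCO3, TSPAN15; receptors whose ligands are not enriched in any
niche population: LGALS3BP, CD96, CD274, CD3D) applied to a 38-gene candidate
pool (13 shared between bcCML and AML, 18 AML-only, 7 bcCML-only). Only part
of the surviving receptors are publicly named, so the candidate table and the
ligand tables are SYNTHETIC stand-ins: placeholder receptor names (SYNR*),
placeholder ligands (SYNL*) and invented per-category assignments fill the
gaps, constructed so the pool counts and the exclusion arithmetic
(38 -> 22 -> 15) are exact.

Running :func:`reference_cascade` pushes this fixture through the real
cascade operations and returns the auditable ledger.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cascade import ReceptorLedger, exclude_by_ligand, surface_filter
from .destats import bh_adjust
from .ligandmap import LOG2FC_CAP, LigandCall

__all__ = [
    "blacklist_genes",
    "candidate_table",
    "fixture_lr_table",
    "fixture_ligand_calls",
    "reference_cascade",
]

NO_KNOWN_LIGAND = ("MR1", "TMCO3", "TSPAN15")
NO_ENRICHED_LIGAND = ("LGALS3BP", "CD96", "CD274", "CD3D")


def _data_path(name: str):
    return resources.files("nichemapper.data") / name


def blacklist_genes() -> list:
    """The 16-gene misannotation blacklist."""
    text = _data_path("surface_misannotation_blacklist.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def candidate_table() -> pd.DataFrame:
    """38 receptor candidates with disease categories (synthetic stand-in)."""
    with resources.as_file(_data_path("receptor_candidates_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def fixture_lr_table() -> pd.DataFrame:
    """Ligand-receptor rows for the fixture (synthetic stand-in)."""
    with resources.as_file(_data_path("fixture_lr_table_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def fixture_ligand_calls(alpha: float = 0.05, min_pct: float = 0.1) -> list:
    """Ligand enrichment calls for the fixture as LigandCall records."""
    with resources.as_file(_data_path("fixture_ligand_calls_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    padj = bh_adjust(df["p"].to_numpy())
    calls = []
    for (_, row), q in zip(df.iterrows(), padj):
        passed = bool(q < alpha and row.log2fc > 0 and row.pct_in >= min_pct)
        calls.append(
            LigandCall(
                ligand=row.ligand,
                population=row.population,
                stage="pooled",
                log2fc=float(row.log2fc),
                log2fc_capped=min(float(row.log2fc), LOG2FC_CAP),
                p=float(row.p),
                padj=float(q),
                pct_in=float(row.pct_in),
                pct_out=float(row.pct_out),
                passed=passed,
            )
        )
    return calls


def reference_cascade() -> ReceptorLedger:
    """Run the curation cascade on the bundled 38-candidate fixture.

    The candidate pool stands in for genes already confirmed upregulated,
    atlas-annotated and screen-depleted; the cascade applies the blacklist
    and ligand-based exclusions, yielding 22 post-blacklist candidates and
    15 final receptors.
    """
    cand = candidate_table()
    genes = set(cand["gene"])
    categories = dict(zip(cand["gene"], cand["category"]))
    blacklist = set(blacklist_genes())
    kept, removed = surface_filter(genes, atlas=genes, blacklist=blacklist)
    reasons = exclude_by_ligand(kept, fixture_lr_table(), fixture_ligand_calls())
    rows = []
    for g in sorted(genes):
        reason = "misannotated" if g in removed else reasons[g]
        rows.append(
            {
                "gene": g,
                "category": categories[g],
                "upregulated_bc": categories[g] in ("both", "bcCML_only"),
                "upregulated_aml": categories[g] in ("both", "AML_only"),
                "surface": True,
                "screen_dropout": True,
                "blacklisted": g in removed,
                "exclusion_reason": reason,
            }
        )
    ledger = ReceptorLedger(pd.DataFrame(rows))
    ledger.assert_conserved()
    return ledger
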