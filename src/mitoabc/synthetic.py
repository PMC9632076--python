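"""Synthetic observed-style datasets: FASTA + metadata + ground truth.

Generates datasets with the statistical structure the analysis assumes —
13 demes over 5 clades, 113 mitogenomes (59 ancient spanning 14-50 ka BP
plus 54 modern), ~16.3 kb sequences — by simulating one genealogy under a
chosen scenario and embedding the infinite-sites variants into a random
monomorphic reference background, so the full pipeline can run end to end
without any external download.

Encoding: a random reference sequence is drawn over A/C/G/T; at each
variant position the ancestral allele is the reference base and the
derived allele its transition partner (A<->G, C<->T).  The mapping is
bijective per site, so sequence differences — and hence S, pi and Fst —
are exactly those of the underlying 0/1 haplotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import HaplotypeAlignment, simulate_genealogy, drop_mutations
from .demography import (
    DemographicModel,
    ModelParams,
    build_model,
    default_config,
    draw_params,
)

METADATA_COLUMNS = ["sample_id", "deme_id", "clade", "age_years_bp"]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class StudyLayout:
    """Deme layout of the observed-style dataset."""

    deme_ids: tuple[str, ...]
    clades: tuple[str, ...]  # per deme
    ages_years_bp: tuple[float, ...]  # per deme
    n_samples: tuple[int, ...]  # per deme
    seq_length: int

    @property
    def total_samples(self) -> int:
        return sum(self.n_samples)

    @property
    def n_demes(self) -> int:
        return len(self.deme_ids)

    @property
    def clade_labels(self) -> set[str]:
        return set(self.clades)


def default_layout() -> StudyLayout:
    """The packaged default: 13 demes, 5 clades, 113 samples, L = 16,300."""
    cfg = default_config()
    return StudyLayout(
        deme_ids=tuple(d["deme_id"] for d in cfg["demes"]),
        clades=tuple(d["clade"] for d in cfg["demes"]),
        ages_years_bp=tuple(float(d["age"]) for d in cfg["demes"]),
        n_samples=tuple(int(d["n"]) for d in cfg["demes"]),
        seq_length=int(cfg["clock"]["seq_length"]),
    )


@dataclass
class SyntheticDataset:
    """An observed-style dataset plus the truth that generated it."""

    alignment: HaplotypeAlignment
    sequences: dict[str, str]  # sample_id -> full nucleotide sequence
    metadata: pd.DataFrame
    ground_truth: dict

    def write(self, outdir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
        """Write FASTA (80-column wrap), metadata TSV and ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        records = [
            SeqRecord(Seq(self.sequences[sid]), id=sid, description="")
            for sid in self.alignment.sample_ids
        ]
        with open(fasta, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
            writer.write_file(records)
        tsv = outdir / f"{prefix}_metadata.tsv"
        self.metadata.to_csv(tsv, sep="\t", index=False)
        truth = outdir / f"{prefix}_truth.json"
        truth.write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True))
        return {"fasta": fasta, "metadata": tsv, "truth": truth}


def _layout_config(layout: StudyLayout, base: dict | None = None) -> dict:
    """Overlay a layout onto a model configuration's deme section."""
    cfg = base if base is not None else default_config()
    by_id = {d["deme_id"]: d for d in cfg["demes"]}
    if set(layout.deme_ids) != set(by_id):
        raise ValueError(
            "layout deme ids do not match the model configuration; supply a "
            "matching configuration"
        )
    for deme_id, clade, age, n in zip(
        layout.deme_ids, layout.clades, layout.ages_years_bp, layout.n_samples
    ):
        d = by_id[deme_id]
        d["clade"], d["age"], d["n"] = clade, age, n
    cfg["clock"]["seq_length"] = layout.seq_length
    return cfg


def generate_observed(
    model_name: str,
    params: ModelParams | None,
    layout: StudyLayout,
    rng: np.random.Generator,
    config: dict | None = None,
) -> SyntheticDataset:
    """Simulate one observed-style dataset under a scenario.

    ``params`` may be a concrete draw; if None, parameters are drawn from
    the scenario's priors.  The dataset is bit-reproducible from the RNG
    state; ground truth records the scenario, the drawn parameters and the
    layout.
    """
    cfg = _layout_config(layout, config)
    model = build_model(model_name, cfg)
    if params is None:
        params = draw_params(model, rng)
    tree = simulate_genealogy(model, params, rng)
    aln = drop_mutations(tree, model.clock, rng)
    sequences = _embed_in_reference(aln, rng)
    age_by_deme = dict(zip(layout.deme_ids, layout.ages_years_bp))
    clade_by_deme = dict(zip(layout.deme_ids, layout.clades))
    metadata = pd.DataFrame(
        {
            "sample_id": aln.sample_ids,
            "deme_id": aln.deme_ids,
            "clade": [clade_by_deme[d] for d in aln.deme_ids],
            "age_years_bp": [int(age_by_deme[d]) for d in aln.deme_ids],
        }
    )
    ground_truth = {
        "model": model_name,
        "params": params.as_flat_dict(),
        "layout": {
            "deme_ids": list(layout.deme_ids),
            "n_samples": list(layout.n_samples),
            "seq_length": layout.seq_length,
        },
    }
    return SyntheticDataset(
        alignment=aln, sequences=sequences, metadata=metadata,
        ground_truth=ground_truth,
    )


def _embed_in_reference(
    aln: HaplotypeAlignment, rng: np.random.Generator
) -> dict[str, str]:
    """Embed 0/1 variants into a random monomorphic nucleotide background."""
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=aln.seq_length)
    derived = np.array([_TRANSITION[b] for b in ref])
    seqs: dict[str, str] = {}
    pos0 = (aln.positions - 1 if aln.positions is not None
            else np.empty(0, dtype=int))
    for i, sid in enumerate(aln.sample_ids):
        seq = ref.copy()
        hit = pos0[aln.matrix[i] == 1]
        seq[hit] = derived[hit]
        seqs[sid] = "".join(seq)
    return seqs


def read_observed(
    fasta_path: str | Path, metadata_path: str | Path
) -> HaplotypeAlignment:
    """Read an aligned FASTA plus metadata TSV into a HaplotypeAlignment.

    The metadata must carry columns sample_id, deme_id, clade,
    age_years_bp, one row per FASTA record.  Sequences are encoded as
    A/C/G/T codes 0..3 (other symbols raise); per-site statistics are
    normalised by the alignment length.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("FASTA records are not aligned (unequal lengths)")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks columns {missing_cols}")
    deme_by_sample = dict(zip(meta["sample_id"], meta["deme_id"]))
    unknown = [r.id for r in records if r.id not in deme_by_sample]
    if unknown:
        raise ValueError(f"FASTA records absent from metadata: {unknown[:5]}")
    if len(meta) != len(records):
        raise ValueError(
            f"{len(meta)} metadata rows for {len(records)} FASTA records"
        )
    L = lengths.pop()
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.empty((len(records), L), dtype=np.uint8)
    for i, r in enumerate(records):
        s = str(r.seq).upper()
        try:
            mat[i] = [code[c] for c in s]
        except KeyError as exc:
            raise ValueError(
                f"record {r.id!r} contains non-ACGT symbol {exc}"
            ) from None
    # keep only variable columns; per-site stats still use full L
    variable = np.flatnonzero((mat != mat[0]).any(axis=0))
    return HaplotypeAlignment(
        sample_ids=[r.id for r in records],
        deme_ids=[str(deme_by_sample[r.id]) for r in records],
        matrix=mat[:, variable],
        seq_length=L,
        positions=(variable + 1).astype(np.int64),
    )
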