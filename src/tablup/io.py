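"""Plain-text readers/writers for simulator and predictor artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_sim import GeneticMap, Population, SimulatedData, TraitArchitecture
from .relmat import RelationshipMatrix

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_plink",
    "write_pedigree_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_effects_csv",
    "read_effects_csv",
    "write_trait_csv",
    "write_grm",
    "read_grm",
]


def write_genotypes_tsv(path, ids, Z) -> None:
    """Individuals x markers TSV with -1/0/1 genotype codes."""
    df = pd.DataFrame(np.asarray(Z), index=np.asarray(ids))
    df.columns = [f"m{k}" for k in range(df.shape[1])]
    df.to_csv(path, sep="\t", index_label="id")


def read_genotypes_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df.index.to_numpy(), df.to_numpy(dtype=np.int8)


def write_plink(prefix, pop: Population, gmap: GeneticMap) -> None:
    """PLINK .ped/.map pair for the marker panel (positions Morgan -> cM)."""
    prefix = Path(prefix)
    markers = gmap.marker_loci
    with open(prefix.with_suffix(".map"), "w") as fh:
        for k, j in enumerate(markers):
            cm = gmap.positions[j] * 100.0
            bp = int(round(gmap.positions[j] * 1_000_000))
            fh.write(f"{gmap.chromosome[j] + 1}\tm{k}\t{cm:.6f}\t{bp}\n")
    hap = pop.haplotypes[:, :, markers]
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(pop.n_individuals):
            sire = pop.sire[i] if pop.sire[i] >= 0 else 0
            dam = pop.dam[i] if pop.dam[i] >= 0 else 0
            sex = 1 if pop.sex[i] == 0 else 2
            phen = pop.phenotypes[i] if pop.phenotypes is not None else np.nan
            phen_s = "-9" if np.isnan(phen) else f"{phen:.6f}"
            alleles = " ".join(
                f"{hap[i, 0, k]} {hap[i, 1, k]}" for k in range(len(markers))
            )
            fh.write(f"1 {pop.ids[i]} {sire} {dam} {sex} {phen_s} {alleles}\n")


def write_pedigree_csv(path, pop: Population) -> None:
    pd.DataFrame(
        {
            "id": pop.ids,
            "sire": pop.sire,
            "dam": pop.dam,
            "generation": pop.generation,
        }
    ).to_csv(path, index=False)


def write_phenotypes_csv(path, pop: Population, column: str = "phenotype") -> None:
    values = pop.phenotypes if column == "phenotype" else pop.tbv
    df = pd.DataFrame({"id": pop.ids, column: values})
    if column == "phenotype":
        df = df.dropna()
    df.to_csv(path, index=False)


def read_phenotypes_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(dtype=float)


def write_effects_csv(path, effects, gmap: GeneticMap | None = None) -> None:
    N = len(effects.g_hat)
    cols = {
        "marker": np.arange(N),
        "g_hat": effects.g_hat,
        "weight": effects.variance_weights,
    }
    if gmap is not None:
        markers = gmap.marker_loci
        cols["chromosome"] = gmap.chromosome[markers] + 1
        cols["position"] = gmap.positions[markers]
    df = pd.DataFrame(cols)
    df.attrs["method"] = effects.method
    with open(path, "w") as fh:
        fh.write(f"# method={effects.method} b_hat={effects.b_hat!r}\n")
        df.to_csv(fh, index=False)


def read_effects_csv(path):
    from .effects import MarkerEffects

    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    return MarkerEffects(
        method=meta.get("method", "unknown"),
        g_hat=df["g_hat"].to_numpy(),
        variance_weights=df["weight"].to_numpy(),
        b_hat=float(meta.get("b_hat", "nan")),
    )


def write_grm(prefix, rm: RelationshipMatrix, n_markers: int | None = None) -> None:
    """GCTA-like lower-triangle text (i, j, n_markers, value) + dense TSV
    + sidecar metadata JSON."""
    prefix = Path(prefix)
    n = rm.n
    nm = n_markers if n_markers is not None else len(rm.weights)
    ids = rm.ids if rm.ids is not None else np.arange(n)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{nm}\t{rm.values[i, j]:.10g}\n")
    pd.DataFrame(rm.values, index=ids, columns=ids).to_csv(
        f"{prefix}.dense.tsv", sep="\t"
    )
    meta = {
        "scheme": rm.scheme,
        "n_individuals": int(n),
        "n_markers": int(nm),
        "mean_ibs": rm.mean_ibs,
        "ids": [int(x) for x in ids],
        "weights": [float(w) for w in rm.weights],
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh)


def read_grm(prefix) -> RelationshipMatrix:
    prefix = Path(prefix)
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    n = meta["n_individuals"]
    values = np.zeros((n, n))
    data = np.loadtxt(f"{prefix}.grm.txt")
    i = data[:, 0].astype(int) - 1
    j = data[:, 1].astype(int) - 1
    values[i, j] = data[:, 3]
    values[j, i] = data[:, 3]
    return RelationshipMatrix(
        values=values,
        scheme=meta["scheme"],
        weights=np.asarray(meta["weights"], dtype=float),
        mean_ibs=meta["mean_ibs"],
        ids=np.asarray(meta["ids"]),
    )


def write_dataset(outdir, data: SimulatedData) -> None:
    """All artifacts of one simulated replicate, in the text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes_tsv(outdir / "genotypes.tsv", data.pop.ids, data.Z)
    write_pedigree_csv(outdir / "pedigree.csv", data.pop)
    write_phenotypes_csv(outdir / "phenotypes.csv", data.pop)
    write_phenotypes_csv(outdir / "tbv.csv", data.pop, column="tbv")
    write_trait_csv(outdir / "trait.csv", data.arch, data.gmap)


def write_trait_csv(path, arch: TraitArchitecture, gmap: GeneticMap) -> None:
    loci = gmap.qtl_loci[arch.slot_indices]
    pd.DataFrame(
        {
            "slot": arch.slot_indices,
            "chromosome": gmap.chromosome[loci] + 1,
            "position": gmap.positions[loci],
            "effect": arch.effects,
            "freq2_gen1": arch.freq2,
        }
    ).to_csv(path, index=False)
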