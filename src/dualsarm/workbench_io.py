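"""Shared I/O, run configuration, and end-to-end pipeline orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import __version__
from .errors import ContractError, ParseError
from .fragmentation import Molecule, build_compound_index, canonicalize
from . import dual_activity, freewilson_qsar, generative, mgm, sarm_core, synthetic_data

logger = logging.getLogger(__name__)


def read_compound_table(
    path,
    fmt: str = "smi",
    separator: str = "\t",
    smiles_column: str = "smiles",
    id_column: str = "id",
    potency_columns: list[str] | None = None,
    sdf_potency_property: str | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a delimited SMILES table or an SDF into a canonicalized table.

    Returns columns ``id``, ``smiles`` plus any requested potency columns.
    In strict mode an unparsable structure is an error; in lenient mode it
    is logged and dropped.
    """
    if fmt == "smi":
        table = pd.read_csv(path, sep=separator)
        if table.empty:
            logger.warning("empty compound table: %s", path)
            return pd.DataFrame(columns=["id", "smiles"])
        for col in [smiles_column, id_column] + (potency_columns or []):
            if col not in table.columns:
                raise ContractError(
                    f"column {col!r} missing; available: {list(table.columns)}"
                )
        records = [
            (str(r[id_column]), str(r[smiles_column]),
             {c: float(r[c]) for c in potency_columns or []})
            for _, r in table.iterrows()
        ]
    elif fmt == "sdf":
        records = []
        for n, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                if strict:
                    raise ParseError(f"record {n} of {path} is unreadable")
                logger.warning("record %d of %s dropped (unreadable)", n, path)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{n:05d}"
            pot = {}
            if sdf_potency_property and mol.HasProp(sdf_potency_property):
                pot[sdf_potency_property] = float(mol.GetProp(sdf_potency_property))
            records.append((cid, Chem.MolToSmiles(mol), pot))
    else:
        raise ContractError(f"unknown format {fmt!r}; use 'smi' or 'sdf'")

    rows, rejected = [], 0
    for cid, smi, pot in records:
        try:
            can = canonicalize(smi)
        except ParseError:
            if strict:
                raise
            rejected += 1
            logger.warning("compound %s rejected: bad SMILES %r", cid, smi)
            continue
        rows.append({"id": cid, "smiles": can, **pot})
    logger.info("read %d compounds (%d rejected) from %s", len(rows), rejected, path)
    return pd.DataFrame(rows)


def build_index_from_file(path) -> "IndexTable":
    from .fragmentation import IndexTable

    return IndexTable.from_json(Path(path).read_text())


@dataclass
class RunConfig:
    """One knob per run: the global seed fans out to per-stage seeds by
    fixed offsets, so every stage is individually reproducible."""

    seed: int = 0
    out_dir: str = "dualsarm_run"
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    generative_epochs: int = 12
    finetune_epochs: int = 8
    n_generated_samples: int = 150
    max_new_keys: int = 12
    max_new_values: int = 9
    top_n: int = 10
    skip_generative: bool = False
    skip_mgm: bool = False
    version: str = __version__

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow on a synthetic data set, writing artifacts.

    Stages: generate data -> fragment/index -> SAR matrices -> fragment
    corpora -> pretrain/fine-tune generators -> generate fragments ->
    expand the densest matrix -> local Free-Wilson predictions -> per-
    target potency models -> dual-target prioritization -> grid-map SVG.
    A manifest with the config and per-artifact hashes is written last;
    a stage failure halts the run with the stage named, keeping partial
    artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "init"

    def write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        artifacts[name] = _sha256(p)

    try:
        stage = "synthetic-data"
        spec = synthetic_data.SyntheticSpec(
            **{"seed": config.stage_seed(1), **config.synthetic}
        )
        dataset = synthetic_data.gen_analog_series(spec)
        write("compounds.csv", dataset.table.to_csv(index=False))

        stage = "fragment-index"
        index = build_compound_index(
            dataset.compounds, potencies=dataset.potency_records()
        )
        write("index.json", index.to_json())

        stage = "build-sarms"
        groups = sarm_core.group_analogous_cores(sarm_core.fragment_cores(index))
        sarms = sarm_core.build_sarms(groups, index)
        if not sarms:
            raise ContractError("no SAR matrix could be built from the data set")
        sarms.sort(key=lambda s: (-s.n_existing(), s.rows[0]))
        for n, sarm in enumerate(sarms):
            write(f"sarm{n:03d}.json", sarm.to_json())
        main = sarms[0]

        expanded = main
        if not config.skip_generative:
            stage = "generative"
            tcfg = generative.TrainingConfig(
                epochs=config.generative_epochs,
                seed=config.stage_seed(2),
                batch_size=16,
            )
            corpus = synthetic_data.gen_fragment_corpus(dataset, "value1")
            state = generative.pretrain(corpus, "value1", tcfg)
            focus = sorted({c.value1 for c in main.cells.values()})
            fcfg = dataclasses.replace(
                tcfg, epochs=config.finetune_epochs, batch_size=min(8, len(focus))
            )
            state = generative.finetune(state, focus, fcfg)
            state.save(out / "value1_model")
            artifacts["value1_model/generator.json"] = _sha256(
                out / "value1_model" / "generator.json"
            )
            new_values = generative.generate_fragments(
                state, seeds=focus, n_samples=config.n_generated_samples,
                seed=config.stage_seed(3),
            )
            ll_min = generative.default_ll_min(state, focus)
            new_values = [
                f for f in generative.filter_by_score(new_values, ll_min)
                if f.novelty and f.smiles not in set(main.cols)
            ][: config.max_new_values]
            new_keys = _novel_keys(main, index, config.max_new_keys)
            write(
                "generated_fragments.json",
                json.dumps(
                    {
                        "ll_min": ll_min,
                        "values": [dataclasses.asdict(f) for f in new_values],
                        "keys": [dataclasses.asdict(f) for f in new_keys],
                    },
                    indent=1,
                ),
            )
            stage = "expand-sarm"
            expanded = sarm_core.expand_sarm(main, new_keys, new_values)
            write("sarm_expanded.json", expanded.to_json())

        stage = "freewilson"
        fw_rows = []
        for target in spec.targets:
            for pred in freewilson_qsar.predict_all_virtual(main, target):
                fw_rows.append(
                    {
                        "row": pred.cell[0], "col": pred.cell[1], "target": target,
                        "predicted": pred.predicted_pIC50,
                        "n_neighborhoods": pred.n_neighborhoods,
                        "spread": pred.spread,
                    }
                )
        write("freewilson_predictions.csv", pd.DataFrame(fw_rows).to_csv(index=False))

        stage = "potency-models"
        t_a, t_b = spec.targets
        feats = dual_activity.featurize(list(dataset.table.smiles))
        models = {}
        for t in (t_a, t_b):
            models[t] = dual_activity.train_potency_model(
                feats,
                dataset.table[f"pIC50_{t}"].to_numpy(),
                target=t,
                seed=config.stage_seed(4),
            )
        write(
            "model_metrics.json",
            json.dumps(
                {
                    t: {"r2_train": m.r2_train, "r2_test": m.r2_test}
                    for t, m in models.items()
                },
                indent=1,
            ),
        )

        stage = "prioritize"
        candidates = dual_activity.prioritize_dual(
            expanded, models[t_a], models[t_b], top_n=config.top_n
        )
        write(
            "candidates.csv",
            pd.DataFrame([dataclasses.asdict(c) for c in candidates]).to_csv(
                index=False
            ),
        )

        if not config.skip_mgm:
            stage = "mgm"
            cells = sarm_core.enumerate_virtual_cells(expanded)
            smiles = [
                c.smiles for c in expanded.cells.values() if c.smiles and c.valid
            ]
            smiles = sorted(set(smiles))
            if len(smiles) >= 3:
                sim = mgm.similarity_matrix(smiles)
                coords = mgm.embed_2d(sim, seed=config.stage_seed(5))
                layout = mgm.grid_assign(coords, mgm.choose_grid_dims(len(smiles)))
                layout = mgm.grid_optimize(layout, sim, seed=config.stage_seed(5))
                preds_a = dual_activity.predict_potency(models[t_a], smiles)
                preds_b = dual_activity.predict_potency(models[t_b], smiles)
                mgm.render_dual(
                    layout.placement,
                    dict(enumerate(preds_a.tolist())),
                    dict(enumerate(preds_b.tolist())),
                    out / "mgm.svg",
                    target_names=(t_a, t_b),
                )
                artifacts["mgm.svg"] = _sha256(out / "mgm.svg")

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "artifacts": dict(sorted(artifacts.items())),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise ContractError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _novel_keys(sarm, index, max_keys: int) -> list:
    """Key1 fragments from the wider index that are not rows of the matrix.

    Used as matrix-expansion rows when the key-side generators are not
    run; scored 0 like other known fragments.
    """
    known = set(sarm.rows)
    pool = [k for k in sorted(index.entries) if k not in known]
    return [
        generative.ScoredFragment(smiles=k, ll_score=0.0, source_role="key1")
        for k in pool[:max_keys]
    ]
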