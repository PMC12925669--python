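"""End-to-end analysis orchestration.

From one configuration: feature matrix -> z-scores -> EBICglasso
networks for every variant (total sample, patients only, healthy
controls only, each diagnostic group, and the total sample without
psychopathological variables) -> bootstrap stability and pruning ->
centralities and edge domain classification -> permutation network
comparisons with Frobenius distances -> a report bundle with a
machine-readable manifest. Idempotent given config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .comparison import frobenius_distance, global_strength, nct
from .errors import SpeechNetError
from .features import FeatureMatrix
from .ggm import network_from_features
from .metrics import classify_edges, node_centralities
from .stability import bootstrap_edge_intervals, prune_edges, sparsity_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

PATIENT_GROUPS = ("MDD", "BD", "SSD")
DEFAULT_CONTRASTS = (
    ("HC", "PATIENTS"),
    ("MDD", "BD"),
    ("MDD", "SSD"),
    ("BD", "SSD"),
)

# fixed per-stage seed offsets derived from the global seed
_STAGE_OFFSET = {"bootstrap": 101, "nct": 211}


@dataclass
class PipelineConfig:
    features_csv: str
    out_dir: str
    gamma: float = 0.5
    bootstrap_B: int = 1000
    nperm: int = 1000
    nlambda: int = 100
    lambda_min_ratio: float = 0.01
    level: float = 0.95
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_CONTRASTS]
    )
    exclude_variables: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        return cls(**data)


def _variant_subjects(fm: FeatureMatrix) -> dict[str, list]:
    if fm.groups is None:
        return {"total": list(fm.values.index)}
    groups = fm.groups
    variants = {"total": list(fm.values.index)}
    patients = list(groups.index[groups.isin(PATIENT_GROUPS)])
    if patients:
        variants["patients"] = patients
    for g in ["HC", *PATIENT_GROUPS]:
        members = list(groups.index[groups == g])
        if members:
            variants[g] = members
    return variants


def _contrast_members(fm: FeatureMatrix, name: str) -> list:
    groups = fm.groups
    if name == "PATIENTS":
        return list(groups.index[groups.isin(PATIENT_GROUPS)])
    return list(groups.index[groups == name])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fm = FeatureMatrix.from_csv(config.features_csv)
    if config.exclude_variables:
        keep = [c for c in fm.values.columns if c not in config.exclude_variables]
        fm = FeatureMatrix(fm.values[keep].copy(),
                           {c: fm.domains[c] for c in keep}, fm.groups)

    manifest: dict = {
        "config": {
            "features_csv": str(config.features_csv),
            "gamma": config.gamma,
            "bootstrap_B": config.bootstrap_B,
            "nperm": config.nperm,
            "nlambda": config.nlambda,
            "lambda_min_ratio": config.lambda_min_ratio,
            "level": config.level,
            "contrasts": [list(c) for c in config.contrasts],
            "exclude_variables": list(config.exclude_variables),
            "seed": config.seed,
        },
        "stage_seeds": {k: config.seed + v for k, v in _STAGE_OFFSET.items()},
        "networks": {},
        "contrasts": {},
    }

    variants = _variant_subjects(fm)
    psych_cols = [c for c, d in fm.domains.items() if d == "psychopathological"]
    variant_inputs = {name: (fm, subjects) for name, subjects in variants.items()}
    if psych_cols:
        no_psych = fm.select(exclude_domains=("psychopathological",))
        variant_inputs["total_no_psychopathology"] = (no_psych,
                                                     list(no_psych.values.index))

    stage = "networks"
    try:
        for name, (fmat, subjects) in variant_inputs.items():
            logger.info("estimating network variant %r (n=%d)", name,
                        len(subjects))
            net = network_from_features(
                fmat, gamma=config.gamma, subjects=subjects,
                nlambda=config.nlambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            complete = fmat.values.loc[subjects].dropna(axis=0, how="any")
            ci = bootstrap_edge_intervals(
                complete, B=config.bootstrap_B, level=config.level,
                gamma=config.gamma,
                seed=manifest["stage_seeds"]["bootstrap"],
                nlambda=config.nlambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            pruned = prune_edges(net, ci)

            net.to_json(out / f"network_{name}.json")
            pruned.to_json(out / f"network_{name}_pruned.json")
            pruned.write_edge_list(out / f"edges_{name}.tsv")
            ci.to_tsv(out / f"edges_ci_{name}.tsv")
            cent = node_centralities(pruned)
            cent.to_csv(out / f"centrality_{name}.csv")
            manifest["networks"][name] = {
                "n": int(net.n),
                "lambda_selected": net.lambda_selected,
                "sparsity_unpruned": sparsity_summary(net),
                "sparsity_pruned": sparsity_summary(pruned),
                "global_strength_pruned": global_strength(pruned),
                "edge_domains": {
                    k: v for k, v in classify_edges(pruned).items()
                    if k != "cross_domain_edges"
                },
            }

        stage = "contrasts"
        if fm.groups is not None:
            for a, b in config.contrasts:
                key = f"{a}_vs_{b}"
                subj_a = _contrast_members(fm, a)
                subj_b = _contrast_members(fm, b)
                if not subj_a or not subj_b:
                    logger.warning("skipping contrast %s: empty group", key)
                    continue
                X_a = fm.values.loc[subj_a].dropna(axis=0, how="any")
                X_b = fm.values.loc[subj_b].dropna(axis=0, how="any")
                res = nct(X_a, X_b, nperm=config.nperm, gamma=config.gamma,
                          seed=manifest["stage_seeds"]["nct"],
                          nlambda=config.nlambda,
                          lambda_min_ratio=config.lambda_min_ratio)
                res.to_json(out / f"nct_{key}.json")
                res.edgewise_table().to_csv(out / f"nct_edges_{key}.tsv",
                                            sep="\t", index=False)
                net_a = network_from_features(fm, gamma=config.gamma,
                                              subjects=subj_a,
                                              nlambda=config.nlambda,
                                              lambda_min_ratio=config.lambda_min_ratio)
                net_b = network_from_features(fm, gamma=config.gamma,
                                              subjects=subj_b,
                                              nlambda=config.nlambda,
                                              lambda_min_ratio=config.lambda_min_ratio)
                manifest["contrasts"][key] = {
                    "M": res.M_observed, "p_M": res.p_M,
                    "S": res.S_observed, "p_S": res.p_S,
                    "frobenius": frobenius_distance(net_a, net_b),
                    "n_a": len(X_a), "n_b": len(X_b),
                }
    except SpeechNetError:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    _write_summary(out, manifest)
    return manifest


def _write_summary(out: Path, manifest: dict) -> None:
    lines = ["# Pipeline summary", ""]
    for name, info in manifest["networks"].items():
        sp = info["sparsity_pruned"]
        lines.append(
            f"- network {name}: n={info['n']}, p={sp['p']}, "
            f"{sp['n_nonzero']}/{sp['n_possible']} edges after pruning "
            f"(sparsity {sp['sparsity']:.4f}), "
            f"global strength {info['global_strength_pruned']:.3f}"
        )
    for key, c in manifest["contrasts"].items():
        lines.append(
            f"- contrast {key}: M={c['M']:.3f} (p={c['p_M']:.3f}), "
            f"S={c['S']:.3f} (p={c['p_S']:.3f}), "
            f"Frobenius={c['frobenius']:.3f}"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
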