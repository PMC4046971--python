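"""Decompose transcriptional variance of the simulated panel.

Fits the five-random-effect mixed model to the log2 FPKM written by
01_simulate_study.py, reports %VE per component under the homoscedastic
and both heteroscedastic residual models, and reproduces the confounding
contrast: on a donor-nested-in-origin design with no true origin effect,
removing the donor component inflates the apparent origin VE severalfold.
"""

import argparse
import json
import os

from ipscvar import io_formats as io
from ipscvar import normalization as nz
from ipscvar import synthetic_data as sd
from ipscvar import variance_components as vc

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--study", default="results/study")
parser.add_argument("--out", default="results/varcomp.json")
args = parser.parse_args()

log2fpkm = io.read_expression_matrix(f"{args.study}/log2fpkm.tsv", "log2fpkm")
meta = io.read_sample_metadata(f"{args.study}/metadata.tsv")
design = vc.build_design(meta)

result = {}
for model in ("homo", "het1", "het2"):
    fit = vc.fit_mixed_model(log2fpkm.values, design, residual_model=model)
    result[model] = {
        "ve": fit.ve,
        "delta2": fit.params.delta2,
        "residual": fit.params.residual,
        "loglik": fit.params.loglik,
    }

print("percent variance explained (homoscedastic residual):")
for comp, ve in sorted(result["homo"]["ve"].items(), key=lambda kv: -kv[1]):
    print(f"  {comp:14s} {100 * ve:5.1f}%")
r1 = result["het1"]["residual"]
print(
    f"heteroscedastic model 1 residuals: adult {r1['adult']:.2f}, "
    f"iPSC {r1['iPSC']:.2f}, ESC {r1['ESC']:.2f} — replicate noise in iPSC "
    "lines is not larger than in adult passages or ESC growths."
)

# confounded companion design: donors nested inside tissue of origin
meta_conf = sd.confounded_ipsc_design()
params = sd.default_variance_params()
params.delta2["origin"] = 0.0
study_conf = sd.simulate_study(sd.SimulationConfig(
    n_genes=2000, design=meta_conf, variance_params=params, seed=args.seed,
))
l2c = nz.log_transform(nz.compute_fpkm(study_conf["counts"]))
dc = study_conf["design"]
full = vc.fit_mixed_model(l2c.values, dc, components=["origin", "donor_ipsc", "batch"])
red = vc.fit_mixed_model(l2c.values, dc, components=["origin", "batch"])
result["confounding"] = {
    "origin_ve_with_donor": full.ve["origin"],
    "origin_ve_without_donor": red.ve["origin"],
}
print(
    f"confounded design (true origin VE = 0): origin VE "
    f"{100 * full.ve['origin']:.1f}% with donor modeled vs "
    f"{100 * red.ve['origin']:.1f}% without — apparent 'memory' of the "
    "source tissue is donor genetic background in disguise."
)

os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
with open(args.out, "w") as fh:
    json.dump(result, fh, indent=2)
print(f"wrote {args.out}")
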