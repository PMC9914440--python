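#!/usr/bin/env python
"""Simulate the QD-SPT raw material for the downstream analyses.

Generates two conditions of quantum-dot trajectories (control: mobile,
weakly confined; treated: slowed and tightly confined, emulating GABA_A_R
pharmacology) at the acquisition settings of the stack (1200 frames, 30 ms,
25 nm localization noise), plus a compartment-mask scene, and writes
localization tables and masks under results/spt/.
"""

from pathlib import Path

from memdyn.io import write_json, write_mask_tiff
from memdyn.pipeline import simulate_condition_trajectories
from memdyn.synthetic import SceneConfig
from memdyn.trajectories import write_trajectories_csv

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "spt"
RAW = ROOT / "scratch" / "spt_raw"  # bulky localization tables stay out of results/
SEED = 20240101

CONDITIONS = {
    "control": {"motion_model": "confined_ou", "diffusion_coeff": 0.10,
                "confinement_radius": 0.40},
    "treated": {"motion_model": "confined_ou", "diffusion_coeff": 0.05,
                "confinement_radius": 0.20},
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RAW.mkdir(parents=True, exist_ok=True)
    for i, (cond, cfg) in enumerate(CONDITIONS.items()):
        trajs = simulate_condition_trajectories(150, cfg, SEED + 1000 * i)
        write_trajectories_csv(trajs, RAW / f"trajectories_{cond}.csv")
        print(f"{cond}: {len(trajs)} trajectories -> scratch/spt_raw/trajectories_{cond}.csv")

    scene = SceneConfig(
        image_shape=(128, 128),
        masks={
            "inhibitory": [((6.0, 6.0), 0.3), ((18.0, 6.0), 0.3)],
            "excitatory": [((12.0, 12.0), 0.3), ((6.0, 18.0), 0.3)],
        },
    )
    for cls, mask in scene.rasterize_masks().items():
        write_mask_tiff(mask, OUT / f"mask_{cls}.tif")
        print(f"mask_{cls}.tif: {int(mask.sum())} pixels on the 190 nm grid")
    write_json({"seed": SEED, "conditions": CONDITIONS}, OUT / "simulation_params.json")


if __name__ == "__main__":
    main()
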