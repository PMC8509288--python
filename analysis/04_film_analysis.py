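"""Generate film scenes across concentrations and analyze them.

Renders synthetic dried-film micrographs (scaled-down spiral loads) at
four magnetite concentrations, runs the spiral detector and aggregate
sizing on each, and compares detected counts against the planted truth.
Scene PNGs with truth sidecars and per-scene reports land in
results/films/.
"""

import json
from pathlib import Path

import numpy as np

from albumag.film import FilmImage, analyze_film, write_report_json
from albumag.synthetic import FilmGeometry, generate_film_image, write_film_scene

RESULTS = Path(__file__).resolve().parent.parent / "results" / "films"
CONCENTRATIONS = [1e-5, 1e-4, 5e-2, 1.0]  # mg/L
SEEDS = range(4)
COUNT_SCALE = 0.1  # scenes carry a tenth of the full-dish spiral load
GEO = FilmGeometry(512, 512, 0.5)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary = []
    for n_mf in CONCENTRATIONS:
        detected, planted, agg_max = [], [], 0.0
        for seed in SEEDS:
            image, truth = generate_film_image(
                n_mf, GEO, seed=seed, count_scale=COUNT_SCALE
            )
            stem = f"film_{n_mf:.0e}_s{seed}"
            write_film_scene(
                image, truth, RESULTS / f"{stem}.png", RESULTS / f"{stem}.json"
            )
            report = analyze_film(
                FilmImage(image, GEO.pixel_size_um), source={"n_mf_mg_L": n_mf}
            )
            write_report_json(report, RESULTS / f"{stem}_report.json")
            detected.append(report.n_spirals)
            planted.append(len(truth.planted_spirals))
            if report.aggregate_diameters:
                agg_max = max(agg_max, max(report.aggregate_diameters))
        summary.append(
            {
                "n_mf_mg_L": n_mf,
                "mean_detected_spirals": float(np.mean(detected)),
                "mean_planted_spirals": float(np.mean(planted)),
                "largest_aggregate_um": agg_max,
            }
        )
        print(
            f"n_MF = {n_mf:8.0e} mg/L: planted {np.mean(planted):5.1f}, "
            f"detected {np.mean(detected):5.1f}, largest aggregate {agg_max:5.1f} um"
        )
    with open(RESULTS / "film_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    counts = [s["mean_detected_spirals"] for s in summary]
    print(
        "\nrise-then-fall ordering reproduced:"
        f" {counts[1] > counts[0] and counts[2] > counts[3]}"
    )
    print(f"outputs in {RESULTS}")


if __name__ == "__main__":
    main()
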