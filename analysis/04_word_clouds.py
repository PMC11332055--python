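"""Semantic t-test word clouds.

For each emotion, every unique word is scored by the cosine between its
embedding and the leave-one-out difference vector separating that emotion's
aggregate semantic representation from the other three; one-sided t-tests
with Bonferroni correction pick the significant words.  On synthetic data
the top words of each emotion should come from that emotion's own lexicon
(shared confusable-pair words may appear under both emotions).
"""

from pathlib import Path

from qcla.pipeline import RunConfig, run_experiment
from qcla.synthetic import GeneratorConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "word_clouds"


def main(seed: int = 42) -> None:
    config = RunConfig(
        generator=GeneratorConfig(seed=seed),
        feature_sets=(),
        seed=seed,
        run_contrast=True,
        outdir=str(OUT),
    )
    report = run_experiment(config)
    table = report["contrast"]["contrast_table"]
    print(f"{report['contrast']['n_unique_words']} unique words, "
          f"{len(table)} significant cloud entries\n")
    for emotion in ("harmony", "satisfaction", "depression", "anxiety"):
        rows = [r for r in table if r["emotion"] == emotion][:5]
        words = ", ".join(f"{r['word']} (t={r['t']:.1f})" for r in rows)
        print(f"{emotion:>12}: {words}")
    print(f"\ncloud table written to {OUT / 'word_clouds.tsv'}")


if __name__ == "__main__":
    main()
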