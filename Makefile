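# Full four-model replication: datasets, kernels, benchmarks, reports.
# Long run (~1-2 h on one CPU); the test suite covers desk-scale versions.

MODELS = radiation flowering boolean netflow
STAGES = generate kernel benchmark report

.PHONY: replicate test acceptance

replicate:
	@for m in $(MODELS); do \
	  for s in $(STAGES); do \
	    echo "== $$m / $$s"; \
	    simkern $$s --config configs/$$m.yaml --outdir runs/$$m || exit 1; \
	  done; \
	done

test:
	python -m pytest -q tests/

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json
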