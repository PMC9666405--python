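gene: Toy
contig: chrT
strand: "+"
locus: [100, 700]
constitutive_chain: ["e2", "e3"]
splice_features: {}
exons:
  - {name: e1, class: five_prime, start: 100, end: 200}
  - {name: e2, class: internal, start: 300, end: 400}
  - {name: e3, class: three_prime, start: 500, end: 700}
isoforms:
  - name: TOY-1
    initiating_exon: e1
    diagnostic_junctions: [e1-e2]
    transcript_exons: [e1, e2, e3]
    annotated: true
junctions:
  - {up: e1, down: e2, isoform: TOY-1}
  - {up: e2, down: e3}
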