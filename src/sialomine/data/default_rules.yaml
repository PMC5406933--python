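# Ordered classification rules: first match wins.
# Keyword reconstruction of the standard tick sialotranscriptome families;
# edit or replace for your own catalogue.
- {category: TE, contains: [transposable element, transposase, retrotransposon, gag-pol]}
- {category: viral_like, contains: [viral, virus]}
- {category: secreted, family: Cement proteins, contains: [cement]}
- {category: secreted, family: GYY family, contains: [gyy]}
- {category: secreted, family: GGY family, contains: [ggy]}
- {category: secreted, family: Glycine rich family, contains: [glycine rich, glycine-rich]}
- {category: secreted, family: Kunitz domain, contains: [kunitz]}
- {category: secreted, family: TIL domain, contains: [til domain, trypsin inhibitor-like]}
- {category: secreted, family: Serpin, contains: [serpin]}
- {category: secreted, family: Thyropin domains, contains: [thyropin]}
- {category: secreted, family: Cystatin, contains: [cystatin]}
- {category: secreted, family: Carboxypeptidase inhibitor, contains: [carboxypeptidase inhibitor]}
- {category: secreted, family: Serine carboxypeptidases, contains: [serine carboxypeptidase]}
- {category: secreted, family: Metalloproteases, contains: [metalloprotease, metalloproteinase, reprolysin]}
- {category: secreted, family: Calpain, contains: [calpain]}
- {category: secreted, family: Serine protease, contains: [serine protease, serine proteinase]}
- {category: secreted, family: Lipocalins/histamine binding proteins, contains: [lipocalin, histamine binding, histamine-binding]}
- {category: secreted, family: Immunoglobulin binding proteins, contains: [immunoglobulin binding, igg binding, ig-binding, igg-binding]}
- {category: secreted, family: Mucins, contains: [mucin]}
- {category: secreted, family: Basic tail family, contains: [basic tail]}
- {category: secreted, family: Antigen 5 family, contains: [antigen 5, antigen-5]}
- {category: secreted, family: Thrombin inhibitor, contains: [thrombin inhibitor]}
- {category: secreted, family: Other secreted proteins, contains: [secreted protein], signal_peptide: true}
- {category: housekeeping, contains: [ribosomal protein, histone, tubulin, actin, elongation factor,
    cytochrome, atp synthase, proteasome, heat shock, ubiquitin, nadh dehydrogenase, polymerase,
    kinase, phosphatase, transcription factor, mitochondrial]}
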