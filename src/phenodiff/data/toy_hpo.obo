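format-version: 1.2
data-version: toy/2024-01-01
ontology: phenodiff/toy-hpo
remark: Synthetic miniature phenotype ontology for tests and examples. Term ids follow the HP namespace and the local hierarchy mirrors the cleft-palate, digit, musculoskeletal, bone-density, ear, nose and neurodevelopmental neighborhoods, including multi-parent terms. Not an official HPO release.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0011297
name: Abnormality of digit
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0011927
name: Short digit
is_a: HP:0011297 ! Abnormality of digit

[Term]
id: HP:0004100
name: Abnormal 2nd finger morphology
is_a: HP:0011297 ! Abnormality of digit

[Term]
id: HP:0001500
name: Broad finger
is_a: HP:0011297 ! Abnormality of digit

[Term]
id: HP:0001217
name: Clubbing
is_a: HP:0011297 ! Abnormality of digit

[Term]
id: HP:0011805
name: Abnormal muscle morphology
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001367
name: Abnormal joint morphology
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0100261
name: Abnormal tendon morphology
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001371
name: Flexion contracture
alt_id: HP:0005185
is_a: HP:0011805 ! Abnormal muscle morphology
is_a: HP:0001367 ! Abnormal joint morphology
is_a: HP:0100261 ! Abnormal tendon morphology

[Term]
id: HP:0012785
name: Flexion contracture of finger
alt_id: HP:0006101
is_a: HP:0001371 ! Flexion contracture
is_a: HP:0011297 ! Abnormality of digit

[Term]
id: HP:0009537
name: Flexion contracture of the 2nd finger
is_a: HP:0012785 ! Flexion contracture of finger
is_a: HP:0004100 ! Abnormal 2nd finger morphology

[Term]
id: HP:0003560
name: Muscular dystrophy
is_a: HP:0011805 ! Abnormal muscle morphology

[Term]
id: HP:0001382
name: Joint hypermobility
is_a: HP:0001367 ! Abnormal joint morphology

[Term]
id: HP:0001771
name: Abnormality of the Achilles tendon
is_a: HP:0100261 ! Abnormal tendon morphology

[Term]
id: HP:0003330
name: Abnormal bone structure
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0011849
name: Abnormal bone ossification
is_a: HP:0003330 ! Abnormal bone structure

[Term]
id: HP:0004348
name: Abnormality of bone mineral density
is_a: HP:0011849 ! Abnormal bone ossification

[Term]
id: HP:0004349
name: Reduced bone mineral density
is_a: HP:0004348 ! Abnormality of bone mineral density

[Term]
id: HP:0000938
name: Osteopenia
is_a: HP:0004349 ! Reduced bone mineral density

[Term]
id: HP:0000939
name: Osteoporosis
is_a: HP:0004349 ! Reduced bone mineral density

[Term]
id: HP:0002753
name: Thin bony cortex
is_a: HP:0003330 ! Abnormal bone structure

[Term]
id: HP:0000400
name: Macrotia
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0002265
name: Large fleshy ears
is_a: HP:0000400 ! Macrotia

[Term]
id: HP:0002360
name: Sleep disturbance
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012759
name: Neurodevelopmental abnormality
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012758
name: Neurodevelopmental delay
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0001249
name: Intellectual disability
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000708
name: Behavioral abnormality
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000366
name: Abnormality of the nose
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000455
name: Broad nasal tip
is_a: HP:0000366 ! Abnormality of the nose

[Term]
id: HP:0000431
name: Wide nasal bridge
is_a: HP:0000366 ! Abnormality of the nose

[Term]
id: HP:0000448
name: Prominent nose
is_a: HP:0000366 ! Abnormality of the nose

[Term]
id: HP:0000426
name: Prominent nasal bridge
is_a: HP:0000366 ! Abnormality of the nose

[Term]
id: HP:0100737
name: Abnormal hard palate morphology
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000202
name: Oral cleft
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000175
name: Cleft palate
is_a: HP:0100737 ! Abnormal hard palate morphology
is_a: HP:0000202 ! Oral cleft

[Term]
id: HP:0000204
name: Cleft upper lip
is_a: HP:0000202 ! Oral cleft

[Term]
id: HP:0100336
name: Median cleft lip and palate
is_a: HP:0000175 ! Cleft palate

[Term]
id: HP:0009999
name: obsolete Contractures of the fingers
is_obsolete: true
replaced_by: HP:0012785
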