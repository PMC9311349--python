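Participant,Age in months,Gender,Sim months 1-3 domain,Sim months 1-3 target,Sim months 4-6 domain,Sim months 4-6 target,Sim months 1-6 domain,Sim months 1-6 target,CF months 1-3 domain,CF months 1-3 target,CF months 4-6 domain,CF months 4-6 target,CF months 1-6 domain,CF months 1-6 target
Participant 1,50.4,Male,88,98,94,91,82,93,80,40,80,50,80,80
Participant 2,60,Male,88,87,94,89,82,84,60,60,60,60,80,60
Participant 3,60,Male,71,96,94,92,76,92,60,40,100,60,80,40
Participant 4,72,Male,71,90,94,96,76,90,60,60,80,40,80,80
Participant 5,48,Male,100,78,94,90,94,91,100,100,60,80,60,50
Participant 6,57.6,Male,100,99,94,96,94,89,80,50,80,60,60,50
Participant 7,66,Female,88,87,94,93,100,91,60,60,60,40,80,40
Participant 8,55.2,Female,88,97,94,91,100,92,100,100,100,80,100,80
Participant 9,31.2,Male,65,98,71,96,53,99,80,80,80,60,100,80
Participant 10,57.6,Male,65,89,71,90,53,60,80,60,100,100,60,60
Participant 11,45.6,Male,94,92,53,99,82,82,80,80,60,80,80,40
Participant 12,50.4,Male,94,96,53,60,82,92,100,40,40,40,80,40
Participant 13,54,Male,71,99,94,87,94,93,60,60,50,50,60,40
Participant 14,46.8,Male,71,60,94,99,94,91,40,40,40,60,40,40
Participant 15,49.2,Male,94,93,88,87,88,92,70,60,40,40,80,50
Participant 16,49.3,Male,94,95,88,91,88,90,100,100,80,60,100,50
Participant 17,33.6,Male,71,91,65,98,88,87,100,100,40,50,40,60
Participant 18,62.4,Male,71,91,65,89,88,91,60,60,60,50,100,60
Participant 19,45.6,Female,88,87,94,85,76,99,80,40,40,40,50,50
Participant 20,37.2,Male,88,91,94,88,88,90,60,80,80,60,80,60
Participant 21,40.8,Male,76,92,88,83,94,92,60,60,60,40,40,40
Participant 22,48,Male,76,90,88,93,94,96,100,100,60,40,100,80
Participant 23,27.6,Male,76,88,88,93,82,97,60,50,40,40,100,80
Participant 24,55.2,Male,76,92,88,81,82,87,80,50,100,60,80,40
Participant 25,54,Male,94,87,100,91,94,90,80,40,40,60,80,60
Participant 26,62.4,Male,94,99,100,92,94,96,80,50,40,50,80,60
Participant 27,48,Male,82,93,82,93,71,91,60,100,40,60,100,100
Participant 28,26.4,Male,82,84,82,84,76,91,80,100,40,40,100,40
Participant 29,56.4,Male,65,91,76,92,71,92,60,40,50,60,60,80
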