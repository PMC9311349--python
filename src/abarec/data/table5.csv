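Participant,Age in months,Gender,Domain code recommendation,Target code recommendation,Relevant percentage of recommended domain code,Relevant percentage of recommended target code
Participant 1,50.4,Male,"2, 4, 5, 14","2.1, 2.3, 4.2, 5.1, 14.1",94.4,80.0
Participant 2,60,Male,"1, 2, 4, 5, 6, 7, 11, 14","0.0, 1.1, 2.1, 2.3, 5.1, 5.13, 5.2, 5.8, 6.1, 7.12, 7.3, 11.1, 14.1, 14.3",83.3,66.6
Participant 3,60,Male,"1, 2, 4, 7, 14","1.3, 2.1, 2.3, 7.12, 14.1, 14.3",94.4,81.4
Participant 4,72,Male,"2, 4, 14, 20","4.2",83.3,85.1
Participant 5,48,Male,"1, 2, 4, 7, 14","2.1, 2.3, 7.12, 14.1, 14.3",94.4,82.4
Participant 6,57.6,Male,"1, 5","5.4, 9.1",66.6,84.2
Participant 7,66,Female,"1, 4, 5, 11","1.1, 4.2, 11.1",77.7,83.3
Participant 8,55.2,Female,"2, 4, 5","2.1, 2.3, 5.1",88.8,89.8
Participant 9,31.2,Male,"1, 4, 5","1.1, 5.1",83.3,87.0
Participant 10,57.6,Male,"1, 2, 4, 5, 17","1.1, 4.2, 5.1",83.3,87.0
Participant 11,45.6,Male,"1, 2, 4, 5, 11, 17","1.1, 2.1, 4.2, 5.1, 11.1, 11.2",88.8,81.5
Participant 12,50.4,Male,"2, 4, 5, 6, 14","4.2, 5.1, 6.3",95.2,87.0
Participant 13,54,Male,"2, 4","2.1, 4.2",66.6,83.3
Participant 14,46.8,Male,"1, 5, 11, 20","1.1, 1.3, 5.1, 5.2, 11.1, 11.2",77.7,80.5
Participant 15,49.2,Male,"4","1.3",55.5,77.2
Participant 16,49.3,Male,"1, 2, 4, 5, 11","1.1, 2.3, 5.1, 11.2",94.4,87.9
Participant 17,33.6,Male,"1, 4, 5, 6, 7","0.0",93.3,58.3
Participant 18,62.4,Male,"4","1.3, 2.1, 2.3, 7.12",77.7,87.9
Participant 19,45.6,Female,"2, 4","4.2, 5.1",72.2,91.6
Participant 20,37.2,Male,"1, 2, 4, 5","1.1, 5.1",88.8,97.8
Participant 21,40.8,Male,"2, 4, 5, 6","5.1, 6.25",88.8,84.2
Participant 22,48,Male,"1, 4, 5","1.1, 5.1",83.3,87.0
Participant 23,27.6,Male,"4, 5","5.1",77.7,82.4
Participant 24,55.2,Male,"2, 4, 5, 6, 14","4.2, 5.1, 6.3",83.3,82.4
Participant 25,54,Male,"1, 4, 5","1.1, 5.1",83.3,87.0
Participant 26,62.4,Male,"1, 2, 4, 5","1.1, 2.1, 5.1",88.2,89.8
Participant 27,48,Male,"7","7.12",77.7,89.8
Participant 28,26.4,Male,"4, 5","5.1",77.7,88.8
Participant 29,56.4,Male,"1, 4, 5","1.1, 5.1",83.3,87.0
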